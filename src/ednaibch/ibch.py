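"""IBCH macroinvertebrate biotic index engine.

The index combines two components computed from kick-net community data:
the variety class CV (an ordinal class of indicator-taxon richness) and the
indicator group GI (the sensitivity value, 1-9, of the most
pollution-intolerant indicator taxon present with at least its minimum
specimen count).  A lookup table maps (GI, CV) to a score from 0 to 20,
which five ordered categories translate into an ecological state from
"bad" to "very good".

The official national lookup tables are distributed with the monitoring
framework, not reproduced here; the default configuration generates a
structurally faithful surrogate (score = min(GI + CV - 1, 20), uniform
variety bins, equal-width categories) and every table can be replaced via
YAML without code changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml

from .datamodel import IndicatorList, KicknetCommunity
from .errors import ConfigError, ValidationError
from .io import default_indicator_list

CATEGORY_LABELS = ("bad", "unsatisfactory", "moderate", "good", "very good")

MAX_CV = 14
MAX_GI = 9


def default_variety_bins(width: int = 4, max_cv: int = MAX_CV
                         ) -> list[tuple[int, int]]:
    """Uniform richness bins: CV = ceil(richness / width), capped."""
    bins = [(1 + width * (c - 1), width * c) for c in range(1, max_cv)]
    bins.append((1 + width * (max_cv - 1), None))  # open-ended top bin
    return bins


def default_score_table(max_gi: int = MAX_GI, max_cv: int = MAX_CV,
                        ceiling: int = 20) -> list[list[int]]:
    """Formula-generated score lookup: score = min(GI + CV - 1, ceiling)."""
    return [
        [min(gi + cv - 1, ceiling) for cv in range(1, max_cv + 1)]
        for gi in range(1, max_gi + 1)
    ]


def default_category_bounds() -> list[tuple[int, int, str]]:
    """Equal-width quintiles of the 0-20 scale."""
    edges = [(0, 4), (5, 8), (9, 12), (13, 16), (17, 20)]
    return [(lo, hi, lab) for (lo, hi), lab in zip(edges, CATEGORY_LABELS)]


@dataclass
class IbchConfig:
    """Configurable tables behind the biotic-index computation."""

    indicators: IndicatorList = field(default_factory=default_indicator_list)
    variety_bins: list[tuple[int, int]] = field(
        default_factory=default_variety_bins
    )
    score_table: list[list[int]] = field(default_factory=default_score_table)
    category_bounds: list[tuple[int, int, str]] = field(
        default_factory=default_category_bounds
    )

    def __post_init__(self) -> None:
        bins = self.variety_bins
        if not bins or bins[0][0] != 1 or bins[-1][1] is not None:
            raise ConfigError("variety bins must start at 1 and end open")
        for (lo, hi), (lo2, _) in zip(bins, bins[1:]):
            if hi is None or lo2 != hi + 1 or hi < lo:
                raise ConfigError("variety bins must be contiguous")
        table = self.score_table
        if len(table) < 1 or any(len(r) != len(bins) for r in table):
            raise ConfigError(
                "score table must have one column per variety class"
            )
        for row in table:
            if any(not 0 <= v <= 20 for v in row):
                raise ConfigError("score table values must lie in 0..20")
            if any(b < a for a, b in zip(row, row[1:])):
                raise ConfigError("score table must be non-decreasing in CV")
        for lower, upper in zip(table, table[1:]):
            if any(u < l for l, u in zip(lower, upper)):
                raise ConfigError("score table must be non-decreasing in GI")
        cats = self.category_bounds
        lo0 = cats[0][0]
        if lo0 != 0:
            raise ConfigError("first category must start at the scale floor")
        for (_, hi, _), (lo, _, _) in zip(cats, cats[1:]):
            if lo != hi + 1:
                raise ConfigError("category intervals must partition the scale")
        if cats[-1][1] < self.max_score:
            raise ConfigError("categories must cover the score range")

    @property
    def max_score(self) -> int:
        return max(max(row) for row in self.score_table)

    @property
    def labels(self) -> list[str]:
        return [lab for _, _, lab in self.category_bounds]


@dataclass
class IbchResult:
    """Per-site biotic-index outcome with all intermediate quantities."""

    site_id: str
    richness: int
    variety_class: int
    indicator_group: int
    score: int
    category: str


def variety_class(richness: int, config: IbchConfig) -> int:
    """Ordinal richness class; 0 is the sentinel for an empty community."""
    if richness < 0:
        raise ValidationError("richness must be >= 0")
    if richness == 0:
        return 0
    for cv, (lo, hi) in enumerate(config.variety_bins, start=1):
        if hi is None or lo <= richness <= hi:
            if richness >= lo:
                return cv
    raise ValidationError(f"no variety bin contains richness {richness}")


def indicator_group(community: KicknetCommunity, ind: IndicatorList) -> int:
    """Sensitivity value of the best qualifying indicator taxon (0 if none).

    A taxon qualifies when its specimen count reaches its configured
    minimum abundance; taxa with a null sensitivity value count toward
    richness only.
    """
    best = 0
    for taxon, count in community.counts.items():
        entry = ind.by_name(taxon)
        if entry.gi_value is None or count < entry.gi_min_abundance:
            continue
        best = max(best, entry.gi_value)
    return best


def ibch_score(community: KicknetCommunity, config: IbchConfig) -> IbchResult:
    """Score one kick-net community: GI x CV lookup on the configured table."""
    ind = config.indicators
    for taxon in community.counts:
        ind.by_name(taxon)  # raises on unknown taxa
    richness = community.richness
    cv = variety_class(richness, config)
    gi = indicator_group(community, ind)
    if gi == 0 or cv == 0:
        score = 0
    else:
        score = config.score_table[gi - 1][cv - 1]
    return IbchResult(
        site_id=community.site_id,
        richness=richness,
        variety_class=cv,
        indicator_group=gi,
        score=score,
        category=classify_score(score, config),
    )


def classify_score(score: int, config: IbchConfig) -> str:
    """Map a numeric score onto one of the five ecological-state labels."""
    top = config.category_bounds[-1][1]
    if not 0 <= score <= top:
        raise ValidationError(f"score {score} outside 0..{top}")
    for lo, hi, label in config.category_bounds:
        if lo <= score <= hi:
            return label
    raise ValidationError(f"no category contains score {score}")


def category_index(label: str, config: IbchConfig) -> int:
    try:
        return config.labels.index(label)
    except ValueError:
        raise ValidationError(f"unknown category label {label!r}")


def score_communities(communities: Sequence[KicknetCommunity],
                      config: Optional[IbchConfig] = None) -> list[IbchResult]:
    config = config or IbchConfig()
    return [ibch_score(c, config) for c in communities]


def load_ibch_config(path, indicators: Optional[IndicatorList] = None
                     ) -> IbchConfig:
    """Load table overrides from YAML; omitted blocks keep their defaults."""
    with open(Path(path), "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    kw = {}
    if indicators is not None:
        kw["indicators"] = indicators
    if "variety_bins" in doc:
        kw["variety_bins"] = [
            (int(lo), None if hi in (None, "inf") else int(hi))
            for lo, hi in doc["variety_bins"]
        ]
    if "score_table" in doc:
        kw["score_table"] = [[int(v) for v in row] for row in doc["score_table"]]
    if "category_bounds" in doc:
        kw["category_bounds"] = [
            (int(lo), int(hi), str(lab)) for lo, hi, lab in doc["category_bounds"]
        ]
    return IbchConfig(**kw)
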