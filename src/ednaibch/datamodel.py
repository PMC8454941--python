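"""Shared data model for the eDNA-to-biotic-index pipeline.

The pipeline starts from an OTU x sample read-count table with replicated
field samples plus negative/positive controls, a per-OTU taxonomy, a
reference list of macroinvertebrate indicator groups, and kick-net specimen
counts per site.  All containers wrap pandas objects and validate their
invariants on construction.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError

SAMPLE_ROLES = ("field", "negative_control", "positive_control")
CONTROL_ROLES = ("negative_control", "positive_control")

#: Phyla surveyed by the macroinvertebrate monitoring framework; used to
#: subset OTUs before taxonomy-free prediction.
DEFAULT_PHYLA = frozenset(
    {"Arthropoda", "Cnidaria", "Porifera", "Bryozoa", "Mollusca"}
)

TAXONOMY_RANKS = ("phylum", "class", "order", "family", "genus", "species")


@dataclass
class ReadCountMatrix:
    """OTU x sample integer read counts with per-sample roles.

    ``counts`` is indexed by OTU id with one column per sample; ``meta`` is
    indexed by sample id with columns ``site_id``, ``replicate_index`` and
    ``role``.  Controls have null site/replicate.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = self.counts.copy()
        self.meta = self.meta.copy()
        self._validate()

    def _validate(self) -> None:
        counts, meta = self.counts, self.meta
        if counts.index.has_duplicates:
            raise ValidationError("duplicate OTU ids in count matrix")
        if counts.columns.has_duplicates:
            raise ValidationError("duplicate sample ids in count matrix")
        arr = counts.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            # allow float input only when integral
            if not np.all(np.isfinite(arr)) or np.any(arr != np.floor(arr)):
                bad = np.argwhere((arr != np.floor(arr)) | ~np.isfinite(arr))
                o, s = bad[0]
                raise FormatErrorAt(counts, o, s, "non-integer count")
            self.counts = counts.astype(np.int64)
            arr = self.counts.to_numpy()
        if arr.size and arr.min() < 0:
            o, s = np.argwhere(arr < 0)[0]
            raise FormatErrorAt(self.counts, o, s, "negative count")
        missing = set(counts.columns) - set(meta.index)
        if missing:
            raise ValidationError(
                f"samples missing from metadata: {sorted(missing)}"
            )
        bad_roles = set(meta["role"]) - set(SAMPLE_ROLES)
        if bad_roles:
            raise ValidationError(f"unknown sample roles: {sorted(bad_roles)}")
        fs = meta.loc[list(counts.columns)]
        fs = fs[fs["role"] == "field"]
        if fs.empty:
            raise ValidationError("no field samples present")
        if fs["site_id"].isna().any() or fs["replicate_index"].isna().any():
            raise ValidationError(
                "every field sample needs site_id and replicate_index"
            )
        pairs = list(zip(fs["site_id"], fs["replicate_index"]))
        if len(pairs) != len(set(pairs)):
            raise ValidationError(
                "(site_id, replicate_index) not unique among field samples"
            )

    # -- convenience accessors -------------------------------------------
    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def samples_with_role(self, *roles: str) -> list[str]:
        meta = self.meta.loc[list(self.counts.columns)]
        return list(meta.index[meta["role"].isin(roles)])

    @property
    def field_samples(self) -> list[str]:
        return self.samples_with_role("field")

    @property
    def control_samples(self) -> list[str]:
        return self.samples_with_role(*CONTROL_ROLES)

    def site_replicates(self) -> dict[str, list[str]]:
        """Map site_id -> its field sample ids, ordered by replicate index."""
        meta = self.meta.loc[self.field_samples]
        out: dict[str, list[str]] = {}
        for site, sub in meta.groupby("site_id", sort=True):
            out[str(site)] = list(sub.sort_values("replicate_index").index)
        return out

    def equals(self, other: "ReadCountMatrix") -> bool:
        return self.counts.equals(other.counts) and _meta_equal(
            self.meta, other.meta
        )


def _meta_equal(a: pd.DataFrame, b: pd.DataFrame) -> bool:
    if list(a.index) != list(b.index):
        return False
    for col in ("site_id", "replicate_index", "role"):
        av, bv = a[col], b[col]
        if not ((av.isna() & bv.isna()) | (av == bv)).all():
            return False
    return True


def FormatErrorAt(counts: pd.DataFrame, o: int, s: int, what: str):
    from .errors import FormatError

    return FormatError(
        f"{what} for OTU {counts.index[o]!r} in sample {counts.columns[s]!r}"
    )


@dataclass(frozen=True)
class IndicatorEntry:
    """One indicator taxon of the biotic-index reference list."""

    name: str
    rank: str  # 'family' or 'phylum'
    group: str  # higher group used in composition tables (e.g. Diptera)
    phylum: str
    gi_value: Optional[int]  # 1..9 sensitivity value, None = variety only
    gi_min_abundance: int = 1


@dataclass
class IndicatorList:
    """Reference list of indicator taxa (families, three phyla)."""

    entries: list[IndicatorEntry]

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"duplicate indicator names: {dupes}")
        for e in self.entries:
            if e.rank not in ("family", "phylum"):
                raise ValidationError(
                    f"indicator {e.name!r}: rank must be family or phylum, "
                    f"got {e.rank!r}"
                )
            if e.gi_value is not None and not 1 <= e.gi_value <= 9:
                raise ValidationError(
                    f"indicator {e.name!r}: gi_value outside 1..9"
                )
            if e.gi_min_abundance < 1:
                raise ValidationError(
                    f"indicator {e.name!r}: gi_min_abundance < 1"
                )

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def by_name(self, name: str) -> IndicatorEntry:
        try:
            return self._index()[name]
        except KeyError:
            raise ValidationError(f"unknown indicator taxon {name!r}")

    def _index(self) -> dict[str, IndicatorEntry]:
        if not hasattr(self, "_idx"):
            self._idx = {e.name: e for e in self.entries}
        return self._idx


@dataclass
class KicknetCommunity:
    """Specimen counts of indicator taxa from kick-net sampling at one site."""

    site_id: str
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for taxon, c in self.counts.items():
            if int(c) != c or c < 0:
                raise ValidationError(
                    f"site {self.site_id}: count for {taxon!r} must be a "
                    f"non-negative integer, got {c!r}"
                )
        self.counts = {t: int(c) for t, c in self.counts.items()}

    def present_taxa(self) -> list[str]:
        return [t for t, c in self.counts.items() if c >= 1]

    @property
    def richness(self) -> int:
        return len(self.present_taxa())


@dataclass(frozen=True)
class FilterConfig:
    """Replicate-consistency filter: keep OTUs seen in >= k of n replicates."""

    k: int = 2
    n: int = 4
    threshold_strategy: str = "max_in_controls"
    pooling: str = "sum"
    negatives_only: bool = False
    min_sample_depth: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.k <= self.n:
            raise ConfigError(f"need 1 <= k <= n, got k={self.k}, n={self.n}")
        if self.threshold_strategy not in ("max_in_controls", "proportional"):
            raise ConfigError(
                f"unknown threshold strategy {self.threshold_strategy!r}"
            )
        if self.pooling not in ("sum", "mean"):
            raise ConfigError(f"unknown pooling {self.pooling!r}")
        if self.min_sample_depth < 0:
            raise ConfigError("min_sample_depth must be >= 0")


@dataclass
class SiteDetectionTable:
    """Site-level OTU presence and pooled reads after filtering."""

    presence: pd.DataFrame  # bool, site x OTU
    pooled_reads: pd.DataFrame  # int, site x OTU
    provenance: Optional[FilterConfig] = None

    def __post_init__(self) -> None:
        p, r = self.presence, self.pooled_reads
        if list(p.index) != list(r.index) or list(p.columns) != list(r.columns):
            raise ValidationError("presence/pooled_reads must be aligned")
        pa = p.to_numpy(dtype=bool)
        ra = r.to_numpy()
        if np.any(ra < 0):
            raise ValidationError("pooled reads must be >= 0")
        if np.any(pa & (ra <= 0)) or np.any(~pa & (ra != 0)):
            raise ValidationError(
                "presence must hold exactly where pooled reads > 0"
            )

    @property
    def site_ids(self) -> list[str]:
        return list(self.presence.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.presence.columns)

    def select_otus(self, otus: Iterable[str]) -> "SiteDetectionTable":
        keep = [o for o in self.presence.columns if o in set(otus)]
        return SiteDetectionTable(
            presence=self.presence[keep],
            pooled_reads=self.pooled_reads[keep],
            provenance=self.provenance,
        )


def make_taxonomy(records: Mapping[str, Mapping[str, Optional[str]]],
                  allow_rank_gaps: bool = False) -> pd.DataFrame:
    """Build a validated taxonomy table from per-OTU rank dicts.

    Each record may carry the six Linnaean ranks plus ``indicator_taxon``.
    The assigned ranks must form a prefix (no species without genus) unless
    ``allow_rank_gaps`` is set for unranked dialects.
    """
    rows = {}
    for otu, rec in records.items():
        row = {r: rec.get(r) for r in TAXONOMY_RANKS}
        row["indicator_taxon"] = rec.get("indicator_taxon")
        rows[otu] = row
    tax = pd.DataFrame.from_dict(rows, orient="index")
    tax = tax.reindex(columns=list(TAXONOMY_RANKS) + ["indicator_taxon"])
    validate_taxonomy(tax, allow_rank_gaps=allow_rank_gaps)
    return tax


def validate_taxonomy(tax: pd.DataFrame, indicators: Optional[IndicatorList] = None,
                      allow_rank_gaps: bool = False) -> None:
    """Check rank-prefix consistency and indicator-link agreement."""
    for col in TAXONOMY_RANKS:
        if col not in tax.columns:
            raise ValidationError(f"taxonomy missing rank column {col!r}")
    if not allow_rank_gaps:
        filled = tax[list(TAXONOMY_RANKS)].notna().to_numpy()
        # a filled rank after a gap breaks the prefix property
        gap_then_filled = (~filled[:, :-1]) & filled[:, 1:]
        bad = np.where(gap_then_filled.any(axis=1))[0]
        if bad.size:
            raise ValidationError(
                f"OTU {tax.index[bad[0]]!r}: assigned rank below an "
                "unassigned one (inconsistent prefix)"
            )
    if indicators is not None and "indicator_taxon" in tax.columns:
        linked = tax[tax["indicator_taxon"].notna()]
        for otu, row in linked.iterrows():
            entry = indicators.by_name(row["indicator_taxon"])
            annotated = row.get(entry.rank)
            if annotated != entry.name:
                raise ValidationError(
                    f"OTU {otu!r} linked to {entry.name!r} but its "
                    f"{entry.rank} annotation is {annotated!r}"
                )


def lowest_assigned_rank(tax: pd.DataFrame) -> pd.Series:
    """Deepest non-null rank per OTU (None when fully unassigned)."""
    out = pd.Series([None] * len(tax), index=tax.index, dtype=object)
    for rank in TAXONOMY_RANKS:  # shallow to deep; later overwrites earlier
        has = tax[rank].notna()
        out[has] = rank
    return out


@dataclass
class RunConfig:
    """Top-level configuration of an end-to-end run."""

    seed: int
    outdir: str
    filter: FilterConfig = field(default_factory=FilterConfig)
    synthetic: Optional[object] = None  # SyntheticConfig, avoids import cycle
    counts_path: Optional[str] = None
    meta_path: Optional[str] = None
    taxonomy_path: Optional[str] = None
    kicknet_path: Optional[str] = None
    indicator_path: Optional[str] = None
    ibch_config_path: Optional[str] = None
    rf_scheme: str = "leave_one_out"
    rf_tune: bool = True

    def __post_init__(self) -> None:
        if self.synthetic is None and not (
            self.counts_path and self.meta_path and self.taxonomy_path
            and self.kicknet_path
        ):
            raise ConfigError(
                "need either a synthetic config or paths to counts, "
                "metadata, taxonomy and kick-net tables"
            )


def asdict_shallow(obj) -> dict:
    """dataclasses.asdict without deep-copying pandas payloads."""
    return {
        f.name: getattr(obj, f.name) for f in dataclasses.fields(obj)
    }
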