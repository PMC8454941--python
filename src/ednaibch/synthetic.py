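"""Paired eDNA / kick-net data generator with a latent site-quality model.

Every site carries a latent ecological-quality score q on the 0-20 index
scale.  Each indicator taxon has a sensitivity threshold t; occurrence is
Bernoulli with logistic probability in (q - t), so pristine sites host more
(and more sensitive) taxa.  Kick-net counts thin true occurrences with a
detection probability and draw specimen numbers from a shifted negative
binomial.  On the molecular side each taxon spawns one to five OTUs (its
dominant lineage is always locally present where the taxon occurs; extra
lineages only sometimes), OTUs are detected per filter replicate with a
fixed probability, and read counts fill a log-normal per-sample depth via a
multinomial over detected OTUs, with non-target OTUs (rotifers and other
bycatch) taking most of the depth.  Controls receive sparse low-level
contamination.  The generator returns the full ground truth so recovery
tests have an unambiguous target.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import truncnorm

from .datamodel import (
    IndicatorList,
    KicknetCommunity,
    ReadCountMatrix,
    TAXONOMY_RANKS,
)
from .errors import ConfigError
from .io import default_indicator_list

# phylum pool for non-target OTUs; weights sum to 1.  Roughly a third fall
# into the five surveyed phyla (they enter the prediction features but are
# not indicator-linked), the rest is typical COI bycatch or unassigned.
_NONTARGET_PHYLA = [
    ("Arthropoda", 0.20), ("Mollusca", 0.10), ("Rotifera", 0.30),
    ("Chordata", 0.10), ("Annelida", 0.05), (None, 0.25),
]


@dataclass
class SyntheticConfig:
    """Study-design parameters of the generator.

    Defaults emulate the monitoring campaign the pipeline targets: 92 sites
    with 4 filter replicates each, 145 indicator taxa, a heavy non-target
    OTU load, latent quality centred at 13.3 (sd 2) on the 0-20 scale, and
    markedly lower per-replicate eDNA detectability than kick-net capture.
    """

    n_sites: int = 92
    n_rep: int = 4
    n_indicator_taxa: int = 145
    n_nontarget_otus: int = 1500
    otus_per_taxon: dict[int, float] = field(
        default_factory=lambda: {1: 0.2, 2: 0.2, 3: 0.2, 4: 0.2, 5: 0.2}
    )
    latent_mean: float = 13.3
    latent_sd: float = 2.0
    latent_bounds: tuple[float, float] = (0.0, 20.0)
    # taxon sensitivity thresholds: t = base + slope * gi + N(0, sd);
    # sensitive (high-gi) taxa need higher quality to occur
    sensitivity_base: float = 16.7
    sensitivity_slope: float = 1.5
    sensitivity_sd: float = 6.0
    occupancy_scale: float = 1.0
    kicknet_detection_prob: float = 0.9
    kicknet_nb_size: float = 1.5
    kicknet_nb_mean: float = 12.5
    edna_replicate_detection_prob: float = 0.45
    extra_otu_site_prob: float = 0.2
    nontarget_site_prob: float = 0.3
    read_depth_mean: float = 20_000.0
    read_depth_sigma: float = 0.4
    indicator_read_boost: float = 4.0
    contamination_rate: float = 0.02
    contamination_weighting: str = "uniform"  # or "abundance"
    n_negative_controls: int = 4
    n_positive_controls: int = 2
    seed: Optional[int] = None
    indicators: Optional[IndicatorList] = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("a seed is mandatory for generation")
        if self.n_sites < 1 or self.n_indicator_taxa < 1:
            raise ConfigError("need at least one site and one taxon")
        if self.n_rep < 1:
            raise ConfigError("need at least one replicate")
        for name in ("kicknet_detection_prob", "edna_replicate_detection_prob",
                     "extra_otu_site_prob", "nontarget_site_prob",
                     "contamination_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if abs(sum(self.otus_per_taxon.values()) - 1.0) > 1e-9:
            raise ConfigError("otus_per_taxon probabilities must sum to 1")
        if self.contamination_weighting not in ("uniform", "abundance"):
            raise ConfigError(
                f"unknown contamination weighting "
                f"{self.contamination_weighting!r}"
            )


@dataclass
class LatentTruth:
    """Ground truth behind one generated dataset."""

    quality: pd.Series  # per site, on the 0-20 scale
    occupancy: pd.DataFrame  # bool, site x indicator taxon
    otu_parent: pd.Series  # otu_id -> indicator taxon name (None: non-target)
    sensitivity: pd.Series  # per taxon threshold t


def _site_ids(n: int) -> list[str]:
    return [f"S{i + 1:03d}" for i in range(n)]


def generate_dataset(config: SyntheticConfig):
    """Generate (ReadCountMatrix, taxonomy, kick-net communities, truth)."""
    rng = np.random.default_rng(config.seed)
    indicators = config.indicators or default_indicator_list()
    if config.n_indicator_taxa > len(indicators):
        raise ConfigError(
            f"requested {config.n_indicator_taxa} indicator taxa but the "
            f"reference list has {len(indicators)}"
        )
    entries = indicators.entries[: config.n_indicator_taxa]
    taxa = [e.name for e in entries]
    S, R, J = config.n_sites, config.n_rep, len(entries)
    sites = _site_ids(S)

    # latent quality and taxon sensitivity
    lo, hi = config.latent_bounds
    a = (lo - config.latent_mean) / config.latent_sd
    b = (hi - config.latent_mean) / config.latent_sd
    q = truncnorm.rvs(a, b, loc=config.latent_mean, scale=config.latent_sd,
                      size=S, random_state=rng)
    gi_eff = np.array([e.gi_value if e.gi_value is not None else 5
                       for e in entries], dtype=float)
    t = (config.sensitivity_base + config.sensitivity_slope * gi_eff
         + rng.normal(0.0, config.sensitivity_sd, J))

    # occupancy and kick-net observation
    p_occ = expit((q[:, None] - t[None, :]) / config.occupancy_scale)
    occ = rng.random((S, J)) < p_occ
    knet_detected = occ & (rng.random((S, J)) < config.kicknet_detection_prob)
    nb_p = config.kicknet_nb_size / (config.kicknet_nb_size
                                     + config.kicknet_nb_mean)
    knet_counts = (1 + rng.negative_binomial(config.kicknet_nb_size, nb_p,
                                             size=(S, J))) * knet_detected
    communities = []
    for i, site in enumerate(sites):
        counts = {taxa[j]: int(knet_counts[i, j])
                  for j in range(J) if knet_counts[i, j] > 0}
        communities.append(KicknetCommunity(site_id=site, counts=counts))

    # molecular OTU inventory: indicator taxa spawn 1..5 OTUs each
    m_choices = sorted(config.otus_per_taxon)
    m_probs = [config.otus_per_taxon[m] for m in m_choices]
    m = rng.choice(m_choices, size=J, p=m_probs)
    parent = np.repeat(np.arange(J), m)
    is_first = np.concatenate([[True] + [False] * (mj - 1) for mj in m])
    n_ind_otus = int(m.sum())
    n_otus = n_ind_otus + config.n_nontarget_otus
    otu_ids = [f"OTU_{i + 1:05d}" for i in range(n_otus)]

    # local OTU presence at each site
    loc_ind = occ[:, parent] & (
        is_first[None, :]
        | (rng.random((S, n_ind_otus)) < config.extra_otu_site_prob)
    )
    loc_nt = rng.random((S, config.n_nontarget_otus)) < config.nontarget_site_prob
    loc = np.concatenate([loc_ind, loc_nt], axis=1)

    # per-replicate detection and read counts
    weights = rng.lognormal(0.0, 1.0, size=(S, n_otus))
    weights[:, :n_ind_otus] *= config.indicator_read_boost
    depth_mu = np.log(config.read_depth_mean) - config.read_depth_sigma ** 2 / 2
    counts = np.zeros((n_otus, S * R), dtype=np.int64)
    sample_ids, meta_rows = [], []
    col = 0
    for i, site in enumerate(sites):
        for r in range(R):
            sid = f"{site}_R{r + 1}"
            sample_ids.append(sid)
            meta_rows.append((sid, site, r + 1, "field"))
            detected = loc[i] & (
                rng.random(n_otus) < config.edna_replicate_detection_prob
            )
            nd = int(detected.sum())
            depth = int(round(rng.lognormal(depth_mu,
                                            config.read_depth_sigma)))
            if nd == 0:
                col += 1
                continue
            depth = max(depth, nd)
            w = weights[i, detected]
            reads = 1 + rng.multinomial(depth - nd, w / w.sum())
            counts[detected, col] = reads
            col += 1

    # control samples with sparse low-level contamination
    field_mean = counts.mean(axis=1)
    control_ids = (
        [f"NC{i + 1}" for i in range(config.n_negative_controls)]
        + [f"PC{i + 1}" for i in range(config.n_positive_controls)]
    )
    control_roles = (
        ["negative_control"] * config.n_negative_controls
        + ["positive_control"] * config.n_positive_controls
    )
    ctrl_counts = np.zeros((n_otus, len(control_ids)), dtype=np.int64)
    total_reads = counts.sum(axis=1).astype(float)
    for c in range(len(control_ids)):
        if config.contamination_rate == 0:
            continue
        if config.contamination_weighting == "uniform":
            hit = rng.random(n_otus) < config.contamination_rate
        else:
            n_hits = rng.binomial(n_otus, config.contamination_rate)
            p = total_reads / total_reads.sum() if total_reads.sum() else None
            idx = rng.choice(n_otus, size=min(n_hits, n_otus), replace=False,
                             p=p)
            hit = np.zeros(n_otus, dtype=bool)
            hit[idx] = True
        cap = np.maximum(1, np.floor(0.01 * field_mean)).astype(np.int64)
        draw = rng.integers(1, cap + 1)
        ctrl_counts[hit, c] = draw[hit]
    for sid, role in zip(control_ids, control_roles):
        meta_rows.append((sid, None, None, role))

    all_counts = pd.DataFrame(
        np.concatenate([counts, ctrl_counts], axis=1),
        index=pd.Index(otu_ids, name="otu_id"),
        columns=sample_ids + control_ids,
    )
    meta = pd.DataFrame(
        meta_rows, columns=["sample_id", "site_id", "replicate_index", "role"]
    ).set_index("sample_id")
    matrix = ReadCountMatrix(counts=all_counts, meta=meta)

    # taxonomy: indicator OTUs inherit their parent taxon's annotation;
    # non-target OTUs get a phylum (or nothing) and no indicator link
    tax_rows = {}
    for o in range(n_ind_otus):
        e = entries[parent[o]]
        row = {r: None for r in TAXONOMY_RANKS}
        row["phylum"] = e.phylum
        if e.rank == "family":
            row["family"] = e.name
        row["indicator_taxon"] = e.name
        tax_rows[otu_ids[o]] = row
    nt_phyla = [p for p, _ in _NONTARGET_PHYLA]
    nt_weights = [w for _, w in _NONTARGET_PHYLA]
    nt_choice = rng.choice(len(nt_phyla), size=config.n_nontarget_otus,
                           p=nt_weights)
    for k in range(config.n_nontarget_otus):
        row = {r: None for r in TAXONOMY_RANKS}
        row["phylum"] = nt_phyla[nt_choice[k]]
        row["indicator_taxon"] = None
        tax_rows[otu_ids[n_ind_otus + k]] = row
    taxonomy = pd.DataFrame.from_dict(tax_rows, orient="index")
    taxonomy = taxonomy.reindex(
        columns=list(TAXONOMY_RANKS) + ["indicator_taxon"]
    )
    taxonomy.index.name = "otu_id"

    truth = LatentTruth(
        quality=pd.Series(q, index=sites, name="quality"),
        occupancy=pd.DataFrame(occ, index=sites, columns=taxa),
        otu_parent=pd.Series(
            [taxa[parent[o]] for o in range(n_ind_otus)]
            + [None] * config.n_nontarget_otus,
            index=otu_ids, name="parent_taxon",
        ),
        sensitivity=pd.Series(t, index=taxa, name="sensitivity"),
    )
    return matrix, taxonomy, communities, truth


def truth_summary(truth: LatentTruth) -> pd.DataFrame:
    """Per-site latent quality and true indicator richness."""
    return pd.DataFrame({
        "site_id": truth.quality.index,
        "quality": truth.quality.to_numpy(),
        "true_richness": truth.occupancy.sum(axis=1).to_numpy(),
    }).set_index("site_id")
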