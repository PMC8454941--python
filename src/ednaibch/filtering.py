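"""Data-cleaning cascade for replicated eDNA metabarcoding count tables.

Order of operations: (1) per-OTU read thresholds derived from negative and
positive controls, (2) optional removal of weak samples, (3) k-of-n
replicate-consistency detection per site with replicate pooling, and
(4) taxonomic restriction to indicator taxa or to the surveyed phyla.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import (
    DEFAULT_PHYLA,
    FilterConfig,
    IndicatorList,
    ReadCountMatrix,
    SiteDetectionTable,
)
from .errors import ConfigError, ValidationError

log = logging.getLogger(__name__)


@dataclass
class OtuThresholds:
    """Per-OTU detection thresholds computed from control samples.

    Under ``max_in_controls`` the value is an absolute read count that is
    subtracted from every field sample; under ``proportional`` it is the
    fraction of the OTU's total reads observed in controls, and a count is
    kept only when it reaches that fraction of its sample's depth.
    """

    values: pd.Series  # indexed by otu_id
    strategy: str

    def __post_init__(self) -> None:
        if (self.values < 0).any():
            raise ValidationError("thresholds must be >= 0")


def compute_otu_thresholds(matrix: ReadCountMatrix,
                           strategy: str = "max_in_controls",
                           negatives_only: bool = False) -> OtuThresholds:
    """Derive per-OTU thresholds from reads observed in control samples.

    ``max_in_controls``: the maximum read count of the OTU over all control
    samples (0 with no controls).  ``proportional``: control reads divided
    by the OTU's total reads over all samples (0/0 -> 0).
    """
    if strategy not in ("max_in_controls", "proportional"):
        raise ConfigError(f"unknown threshold strategy {strategy!r}")
    controls = (
        matrix.samples_with_role("negative_control")
        if negatives_only
        else matrix.control_samples
    )
    counts = matrix.counts
    if strategy == "max_in_controls":
        if controls:
            vals = counts[controls].max(axis=1).astype(np.int64)
        else:
            vals = pd.Series(0, index=counts.index, dtype=np.int64)
    else:
        total = counts.sum(axis=1).astype(float)
        in_controls = (
            counts[controls].sum(axis=1).astype(float)
            if controls
            else pd.Series(0.0, index=counts.index)
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = (in_controls / total).fillna(0.0)
        vals[total == 0] = 0.0
    log.info(
        "thresholds computed: strategy=%s controls=%d nonzero=%d",
        strategy, len(controls), int((vals > 0).sum()),
    )
    return OtuThresholds(values=vals, strategy=strategy)


def apply_thresholds(matrix: ReadCountMatrix,
                     thresholds: OtuThresholds) -> ReadCountMatrix:
    """Apply control-based thresholds; zero control columns after use."""
    missing = set(matrix.otu_ids) - set(thresholds.values.index)
    if missing:
        raise ValidationError(
            f"thresholds missing for OTUs: {sorted(missing)[:5]}"
        )
    counts = matrix.counts.copy()
    th = thresholds.values.loc[counts.index]
    fields = matrix.field_samples
    if thresholds.strategy == "max_in_controls":
        sub = counts[fields].to_numpy() - th.to_numpy()[:, None]
        counts[fields] = np.maximum(sub, 0)
    else:
        arr = counts[fields].to_numpy(dtype=np.int64)
        depth = arr.sum(axis=0)  # per-sample column totals
        minimum = th.to_numpy()[:, None] * depth[None, :]
        counts[fields] = np.where(arr >= minimum, arr, 0)
    controls = matrix.control_samples
    if controls:
        counts[controls] = 0
    removed = int((matrix.counts[fields] > 0).sum().sum()
                  - (counts[fields] > 0).sum().sum())
    log.info("thresholds applied: %d field detections removed", removed)
    return ReadCountMatrix(counts=counts, meta=matrix.meta)


def drop_weak_samples(matrix: ReadCountMatrix,
                      min_sample_depth: int) -> ReadCountMatrix:
    """Remove field samples whose total reads fall below a depth cutoff."""
    if min_sample_depth <= 0:
        return matrix
    depth = matrix.counts.sum(axis=0)
    weak = [
        s for s in matrix.field_samples if depth[s] < min_sample_depth
    ]
    if weak:
        log.warning("dropping %d weak samples (depth < %d): %s",
                    len(weak), min_sample_depth, weak)
    keep = [s for s in matrix.sample_ids if s not in set(weak)]
    return ReadCountMatrix(counts=matrix.counts[keep],
                           meta=matrix.meta.loc[keep])


def collapse_replicates(matrix: ReadCountMatrix,
                        fc: FilterConfig) -> SiteDetectionTable:
    """Site-level detection: OTU present iff nonzero in >= k of n replicates.

    Pooled reads are summed (default) over the site's replicates wherever
    the OTU is detected, else 0.  Sites with fewer than k replicates are
    excluded with a warning.
    """
    if fc.k > fc.n:
        raise ConfigError(f"k={fc.k} exceeds n={fc.n}")
    site_reps = matrix.site_replicates()
    too_many = {s: reps for s, reps in site_reps.items() if len(reps) > fc.n}
    if too_many:
        raise ValidationError(
            f"sites with more than n={fc.n} replicates: {sorted(too_many)}"
        )
    sites, rows_presence, rows_pooled = [], [], []
    for site, reps in site_reps.items():
        if len(reps) < fc.k:
            log.warning(
                "site %s excluded: %d replicate(s) available, k=%d",
                site, len(reps), fc.k,
            )
            continue
        sub = matrix.counts[reps].to_numpy()
        detections = (sub > 0).sum(axis=1)
        present = detections >= fc.k
        if fc.pooling == "sum":
            pooled = sub.sum(axis=1)
        else:  # mean pooling, ceil keeps presence <=> pooled > 0
            pooled = np.ceil(sub.sum(axis=1) / len(reps)).astype(np.int64)
        pooled = np.where(present, pooled, 0)
        sites.append(site)
        rows_presence.append(present)
        rows_pooled.append(pooled)
    if not sites:
        raise ValidationError("no site has enough replicates")
    presence = pd.DataFrame(
        np.vstack(rows_presence), index=sites, columns=matrix.otu_ids
    )
    pooled = pd.DataFrame(
        np.vstack(rows_pooled).astype(np.int64),
        index=sites, columns=matrix.otu_ids,
    )
    return SiteDetectionTable(presence=presence, pooled_reads=pooled,
                              provenance=fc)


def restrict_to_indicators(table: SiteDetectionTable, tax: pd.DataFrame,
                           ind: IndicatorList) -> SiteDetectionTable:
    """Keep only OTUs linked to an indicator taxon of the reference list."""
    names = set(ind.names)
    linked = tax["indicator_taxon"]
    keep = [
        o for o in table.otu_ids
        if o in tax.index and linked.get(o) is not None
        and linked.get(o) in names
    ]
    log.info("indicator restriction: %d -> %d OTUs",
             len(table.otu_ids), len(keep))
    return table.select_otus(keep)


def restrict_to_phyla(table: SiteDetectionTable, tax: pd.DataFrame,
                      phyla: frozenset = DEFAULT_PHYLA) -> SiteDetectionTable:
    """Keep OTUs whose phylum annotation falls in the surveyed phyla."""
    keep = [
        o for o in table.otu_ids
        if o in tax.index and tax.at[o, "phylum"] in phyla
    ]
    log.info("phylum restriction to %s: %d -> %d OTUs",
             sorted(phyla), len(table.otu_ids), len(keep))
    return table.select_otus(keep)


def stringency_profile(matrix: ReadCountMatrix, n: int) -> pd.DataFrame:
    """Mean pooled reads and OTU count per site for each k = 1..n.

    Emulates the sensitivity analysis of detection-stringency choices:
    richness and depth per site are non-increasing in k because the k-of-n
    detection sets are nested.
    """
    rows = []
    for k in range(1, n + 1):
        fc = FilterConfig(k=k, n=n)
        try:
            table = collapse_replicates(matrix, fc)
        except ValidationError:
            continue
        rows.append({
            "k": k,
            "mean_reads_per_site":
                float(table.pooled_reads.sum(axis=1).mean()),
            "mean_otus_per_site":
                float(table.presence.sum(axis=1).mean()),
        })
    return pd.DataFrame(rows, columns=["k", "mean_reads_per_site",
                                       "mean_otus_per_site"])
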