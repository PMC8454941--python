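"""Alpha- and gamma-diversity comparison between kick-net and eDNA data.

Alpha: per-site indicator-taxon richness from both methods, their linear
relationship, and a paired test for the systematic eDNA detection deficit.
Gamma: pooled composition proportions per indicator higher-group (Diptera,
Ephemeroptera, ...) for both methods, with rank concordance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import (
    IndicatorList,
    KicknetCommunity,
    SiteDetectionTable,
)
from .errors import ValidationError


@dataclass
class RegressionSummary:
    """Two-parameter OLS fit of y on x with small-sample adjusted R^2."""

    slope: float
    intercept: float
    r_squared: float
    adj_r_squared: float
    p_value: float
    n: int


def edna_site_richness(detections: SiteDetectionTable, tax: pd.DataFrame,
                       ind: IndicatorList) -> pd.Series:
    """Distinct indicator taxa per site; OTU multiplicity collapses.

    The detection table should already be restricted to indicator OTUs;
    unlinked OTUs are ignored either way.
    """
    names = set(ind.names)
    links = {
        o: tax.at[o, "indicator_taxon"]
        for o in detections.otu_ids
        if o in tax.index and tax.at[o, "indicator_taxon"] in names
    }
    out = {}
    presence = detections.presence
    for site in detections.site_ids:
        row = presence.loc[site]
        out[site] = len({links[o] for o in links if row[o]})
    return pd.Series(out, name="edna_richness")


def kicknet_site_richness(communities: Sequence[KicknetCommunity]
                          ) -> pd.Series:
    """Indicator taxa with >= 1 specimen per site."""
    return pd.Series(
        {c.site_id: c.richness for c in communities}, name="kicknet_richness"
    )


def richness_table(kicknet: pd.Series, edna: pd.Series) -> pd.DataFrame:
    table = pd.concat([kicknet.rename("kicknet_richness"),
                       edna.rename("edna_richness")], axis=1)
    if table.isna().any().any():
        missing = table[table.isna().any(axis=1)].index.tolist()
        raise ValidationError(f"sites lacking one method: {missing}")
    return table


def richness_regression(x: Sequence[float], y: Sequence[float]
                        ) -> RegressionSummary:
    """OLS of y on x with adjusted R^2 = 1 - (1 - R^2)(n-1)/(n-2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("richness vectors must be equal-length 1-D")
    n = len(x)
    if n < 3:
        raise ValidationError("need at least 3 paired observations")
    if np.ptp(x) == 0:
        raise ValidationError("zero variance in predictor")
    res = stats.linregress(x, y)
    r2 = res.rvalue ** 2
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return RegressionSummary(
        slope=float(res.slope), intercept=float(res.intercept),
        r_squared=float(r2), adj_r_squared=float(adj),
        p_value=float(res.pvalue), n=n,
    )


def paired_richness_test(kicknet: Sequence[float], edna: Sequence[float],
                         method: str = "t") -> tuple[float, float]:
    """Two-sided paired test on kick-net minus eDNA richness.

    Default paired t-test; Wilcoxon signed-rank via ``method='wilcoxon'``.
    All-zero differences are degenerate and reported as p = 1 with a
    warning.
    """
    a = np.asarray(kicknet, dtype=float)
    b = np.asarray(edna, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("paired vectors must have equal length")
    diff = a - b
    if np.all(diff == 0):
        warnings.warn("all paired differences are zero; p-value degenerate")
        return 0.0, 1.0
    if method == "t":
        stat, p = stats.ttest_rel(a, b)
    elif method == "wilcoxon":
        stat, p = stats.wilcoxon(a, b)
    else:
        raise ValidationError(f"unknown paired test {method!r}")
    return float(stat), float(p)


def composition_profiles(edna: SiteDetectionTable,
                         kicknet: Sequence[KicknetCommunity],
                         tax: pd.DataFrame,
                         ind: IndicatorList) -> pd.DataFrame:
    """Pooled (gamma) composition per indicator higher-group, both methods.

    eDNA proportion of a group = pooled reads of its OTUs / total pooled
    indicator reads; kick-net proportion = specimens in the group / total
    specimens.  All sites combined.
    """
    group_of = {e.name: e.group for e in ind}
    names = set(ind.names)
    groups = sorted({e.group for e in ind})

    edna_reads = dict.fromkeys(groups, 0.0)
    for o in edna.otu_ids:
        link = tax.at[o, "indicator_taxon"] if o in tax.index else None
        if link in names:
            edna_reads[group_of[link]] += float(edna.pooled_reads[o].sum())
    knet_counts = dict.fromkeys(groups, 0.0)
    for c in kicknet:
        for taxon, count in c.counts.items():
            if taxon in names:
                knet_counts[group_of[taxon]] += float(count)

    total_e = sum(edna_reads.values())
    total_k = sum(knet_counts.values())
    if total_e == 0 or total_k == 0:
        raise ValidationError("zero total reads/counts in one method")
    rows = []
    for g in groups:
        rows.append({"group": g, "method": "kicknet",
                     "proportion": knet_counts[g] / total_k})
        rows.append({"group": g, "method": "edna",
                     "proportion": edna_reads[g] / total_e})
    frame = pd.DataFrame(rows)
    frame["rank"] = frame.groupby("method")["proportion"].rank(
        method="dense", ascending=False
    ).astype(int)
    return frame


def rank_concordance(profiles: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Dense ranks per method plus tie-corrected Spearman rho."""
    wide = profiles.pivot(index="group", columns="method",
                          values="proportion")
    if wide.isna().any().any():
        raise ValidationError("profiles must share one group universe")
    rho, _ = stats.spearmanr(wide["kicknet"], wide["edna"])
    ranks = pd.DataFrame({
        "kicknet_rank": wide["kicknet"].rank(method="dense", ascending=False),
        "edna_rank": wide["edna"].rank(method="dense", ascending=False),
    })
    return ranks, float(rho)
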