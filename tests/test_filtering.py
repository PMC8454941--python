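"""Control thresholds, replicate-consistency filters and restrictions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from ednaibch import (
    ConfigError,
    FilterConfig,
    ReadCountMatrix,
    apply_thresholds,
    collapse_replicates,
    compute_otu_thresholds,
    restrict_to_indicators,
    restrict_to_phyla,
    stringency_profile,
)
from ednaibch.datamodel import DEFAULT_PHYLA

from conftest import random_matrix


def matrix_from(counts, meta_rows):
    meta = pd.DataFrame(
        meta_rows, columns=["sample_id", "site_id", "replicate_index", "role"]
    ).set_index("sample_id")
    return ReadCountMatrix(counts=counts, meta=meta)


def one_site(replicate_counts, controls=()):
    """Single-OTU matrix with given per-replicate counts and control reads."""
    cols = [f"A_R{i+1}" for i in range(len(replicate_counts))]
    meta = [(c, "A", i + 1, "field") for i, c in enumerate(cols)]
    vals = list(replicate_counts)
    for j, c in enumerate(controls):
        cols.append(f"NC{j+1}")
        meta.append((f"NC{j+1}", None, None, "negative_control"))
        vals.append(c)
    counts = pd.DataFrame([vals], index=["OTU1"], columns=cols)
    return matrix_from(counts, meta)


class TestThresholds:
    def test_no_controls_all_zero(self):
        m = one_site([3, 4, 0, 1])
        th = compute_otu_thresholds(m)
        assert (th.values == 0).all()

    def test_max_in_controls_is_maximum(self):
        m = one_site([10, 10, 10, 10], controls=[3, 5])
        th = compute_otu_thresholds(m, "max_in_controls")
        assert th.values["OTU1"] == 5

    def test_proportional_fraction(self):
        # 10 control reads, 90 field reads -> fraction 0.1
        m = one_site([30, 30, 30, 0], controls=[10])
        th = compute_otu_thresholds(m, "proportional")
        assert th.values["OTU1"] == pytest.approx(0.1)

    def test_unknown_strategy(self):
        with pytest.raises(ConfigError):
            compute_otu_thresholds(one_site([1, 1, 1, 1]), "median")

    def test_zero_thresholds_identity(self):
        m = one_site([3, 4, 0, 1])
        out = apply_thresholds(m, compute_otu_thresholds(m))
        assert out.counts[m.field_samples].equals(
            m.counts[m.field_samples]
        )

    def test_subtraction_floors_at_zero(self):
        m = one_site([4, 9, 0, 6], controls=[5])
        out = apply_thresholds(m, compute_otu_thresholds(m))
        assert list(out.counts.loc["OTU1", m.field_samples]) == [0, 4, 0, 1]
        assert out.counts.loc["OTU1", "NC1"] == 0  # controls zeroed

    def test_proportional_keeps_counts_reaching_fraction(self):
        cols = ["A_R1", "A_R2", "NC1"]
        counts = pd.DataFrame(
            # OTU1: fraction = 30 / (150 + 50 + 30) = 0.1304...;
            # sample column totals are 1000, so the cutoff is ~130 reads
            [[150, 50, 30], [850, 950, 0]],
            index=["OTU1", "OTU2"], columns=cols,
        )
        meta = [("A_R1", "A", 1, "field"), ("A_R2", "A", 2, "field"),
                ("NC1", None, None, "negative_control")]
        m = matrix_from(counts, meta)
        th = compute_otu_thresholds(m, "proportional")
        out = apply_thresholds(m, th)
        assert out.counts.at["OTU1", "A_R1"] == 150  # 150 >= 130.4
        assert out.counts.at["OTU1", "A_R2"] == 0    # 50 < 130.4

    def test_never_increases_counts(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            m = random_matrix(rng, with_controls=True)
            for strategy in ("max_in_controls", "proportional"):
                out = apply_thresholds(
                    m, compute_otu_thresholds(m, strategy)
                )
                assert (
                    out.counts[m.field_samples].to_numpy()
                    <= m.counts[m.field_samples].to_numpy()
                ).all()


def naive_collapse(matrix, k):
    """Independent per-(site, OTU) loop oracle for replicate collapsing."""
    presence, pooled = {}, {}
    for site, reps in matrix.site_replicates().items():
        for otu in matrix.otu_ids:
            vals = [matrix.counts.at[otu, r] for r in reps]
            det = sum(1 for v in vals if v > 0)
            present = det >= k
            presence[(site, otu)] = present
            pooled[(site, otu)] = sum(vals) if present else 0
    return presence, pooled


class TestCollapse:
    def test_hand_example_two_of_four(self):
        m = one_site([0, 3, 7, 0])
        t2 = collapse_replicates(m, FilterConfig(k=2, n=4))
        assert bool(t2.presence.at["A", "OTU1"]) is True
        assert t2.pooled_reads.at["A", "OTU1"] == 10
        t3 = collapse_replicates(m, FilterConfig(k=3, n=4))
        assert bool(t3.presence.at["A", "OTU1"]) is False
        assert t3.pooled_reads.at["A", "OTU1"] == 0

    def test_k1_equals_any_nonzero(self):
        rng = np.random.default_rng(5)
        m = random_matrix(rng)
        t = collapse_replicates(m, FilterConfig(k=1, n=4))
        for site, reps in m.site_replicates().items():
            any_nonzero = (m.counts[reps] > 0).any(axis=1)
            assert (t.presence.loc[site] == any_nonzero).all()

    def test_agrees_with_naive_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(25):
            m = random_matrix(rng)
            for k in range(1, 5):
                t = collapse_replicates(m, FilterConfig(k=k, n=4))
                presence, pooled = naive_collapse(m, k)
                for site in t.site_ids:
                    for otu in t.otu_ids:
                        assert t.presence.at[site, otu] == presence[
                            (site, otu)
                        ]
                        assert t.pooled_reads.at[site, otu] == pooled[
                            (site, otu)
                        ]

    def test_nestedness_across_k(self):
        rng = np.random.default_rng(13)
        for _ in range(25):
            m = random_matrix(rng)
            tables = [
                collapse_replicates(m, FilterConfig(k=k, n=4)).presence
                for k in range(1, 5)
            ]
            for strict, loose in zip(tables[1:], tables[:-1]):
                assert (~strict | loose).all().all()

    def test_k_above_n_rejected(self):
        with pytest.raises(ConfigError):
            FilterConfig(k=5, n=4)


class TestRestrictions:
    def test_indicator_restriction_and_idempotence(self, default_filtered,
                                                   default_dataset,
                                                   indicators):
        _, (_, tax, _, _) = default_dataset
        table, phyla_table, indicator_table = default_filtered
        linked = set(tax.index[tax["indicator_taxon"].notna()])
        assert set(indicator_table.otu_ids) == linked & set(table.otu_ids)
        again = restrict_to_indicators(indicator_table, tax, indicators)
        assert again.otu_ids == indicator_table.otu_ids

    def test_phyla_restriction_keeps_unassigned_family(self,
                                                       default_dataset,
                                                       default_filtered):
        _, (_, tax, _, _) = default_dataset
        table, phyla_table, _ = default_filtered
        kept_phyla = {tax.at[o, "phylum"] for o in phyla_table.otu_ids}
        assert kept_phyla <= DEFAULT_PHYLA
        # non-indicator Arthropoda (family unassigned) are retained
        unlinked_arthropods = [
            o for o in phyla_table.otu_ids
            if tax.at[o, "indicator_taxon"] is None
        ]
        assert unlinked_arthropods

    def test_indicator_subset_of_phyla_when_contained(self, default_filtered,
                                                      default_dataset,
                                                      indicators):
        _, (_, tax, _, _) = default_dataset
        table, phyla_table, _ = default_filtered
        in_five = [
            e.name for e in indicators if e.phylum in DEFAULT_PHYLA
        ]
        sub = restrict_to_indicators(table, tax, indicators)
        sub_five = [
            o for o in sub.otu_ids
            if tax.at[o, "indicator_taxon"] in set(in_five)
        ]
        assert set(sub_five) <= set(phyla_table.otu_ids)


@settings(derandomize=True, max_examples=40, deadline=None)
@given(
    counts=hnp.arrays(np.int64, shape=(6, 12),
                      elements=st.integers(min_value=0, max_value=30)),
    k=st.integers(min_value=1, max_value=4),
)
def test_collapse_properties_hold_for_arbitrary_tables(counts, k):
    """Presence <=> pooled > 0, and k-of-n sets shrink as k grows."""
    cols = [f"{site}_R{r}" for site in ("A", "B", "C") for r in range(1, 5)]
    meta = pd.DataFrame(
        [(c, c.split("_")[0], int(c[-1]), "field") for c in cols],
        columns=["sample_id", "site_id", "replicate_index", "role"],
    ).set_index("sample_id")
    m = ReadCountMatrix(
        counts=pd.DataFrame(counts, index=[f"O{i}" for i in range(6)],
                            columns=cols),
        meta=meta,
    )
    table = collapse_replicates(m, FilterConfig(k=k, n=4))
    assert (table.presence.to_numpy()
            == (table.pooled_reads.to_numpy() > 0)).all()
    if k > 1:
        looser = collapse_replicates(m, FilterConfig(k=k - 1, n=4))
        assert (~table.presence | looser.presence).all().all()


class TestStringency:
    def test_monotone_profile_on_random_matrices(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            m = random_matrix(rng)
            prof = stringency_profile(m, 4)
            otus = prof["mean_otus_per_site"].to_numpy()
            reads = prof["mean_reads_per_site"].to_numpy()
            assert (np.diff(otus) <= 1e-12).all()
            assert (np.diff(reads) <= 1e-12).all()

    def test_single_site_hand_profile(self):
        # three OTUs seen in 4, 2 and 1 of 4 replicates
        cols = [f"A_R{i}" for i in range(1, 5)]
        counts = pd.DataFrame(
            [[1, 1, 1, 1], [2, 0, 2, 0], [5, 0, 0, 0]],
            index=["OTU1", "OTU2", "OTU3"], columns=cols,
        )
        meta = [(c, "A", i + 1, "field") for i, c in enumerate(cols)]
        m = matrix_from(counts, meta)
        prof = stringency_profile(m, 4).set_index("k")
        assert list(prof["mean_otus_per_site"]) == [3, 2, 1, 1]
        # pooled reads: k=1 -> 4+4+5, k=2 -> 4+4, k=3/4 -> 4
        assert list(prof["mean_reads_per_site"]) == [13, 8, 4, 4]
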