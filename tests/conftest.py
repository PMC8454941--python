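import numpy as np
import pandas as pd
import pytest

from ednaibch import (
    FilterConfig,
    ReadCountMatrix,
    SyntheticConfig,
    apply_thresholds,
    collapse_replicates,
    compute_otu_thresholds,
    default_indicator_list,
    generate_dataset,
    restrict_to_indicators,
    restrict_to_phyla,
)


@pytest.fixture(scope="session")
def indicators():
    return default_indicator_list()


@pytest.fixture(scope="session")
def small_dataset():
    """A compact paired dataset for unit-level checks."""
    cfg = SyntheticConfig(seed=11, n_sites=20, n_indicator_taxa=60,
                          n_nontarget_otus=150, read_depth_mean=4000.0)
    return cfg, generate_dataset(cfg)


@pytest.fixture(scope="session")
def default_dataset():
    """Full-size dataset under the default study design (92 sites)."""
    cfg = SyntheticConfig(seed=1)
    return cfg, generate_dataset(cfg)


@pytest.fixture(scope="session")
def default_filtered(default_dataset, indicators):
    """Cleaned 2-of-4 site detections from the default dataset."""
    _, (matrix, tax, comms, truth) = default_dataset
    thresholds = compute_otu_thresholds(matrix)
    cleaned = apply_thresholds(matrix, thresholds)
    table = collapse_replicates(cleaned, FilterConfig(k=2, n=4))
    phyla_table = restrict_to_phyla(table, tax)
    indicator_table = restrict_to_indicators(table, tax, indicators)
    return table, phyla_table, indicator_table


def random_matrix(rng, n_sites=5, n_otus=8, n_rep=4, with_controls=False,
                  rate=2.0):
    """Small random replicated count matrix for brute-force oracles."""
    sample_ids, meta_rows = [], []
    for s in range(n_sites):
        for r in range(n_rep):
            sid = f"T{s + 1:02d}_R{r + 1}"
            sample_ids.append(sid)
            meta_rows.append((sid, f"T{s + 1:02d}", r + 1, "field"))
    if with_controls:
        for c, role in (("NC1", "negative_control"),
                        ("PC1", "positive_control")):
            sample_ids.append(c)
            meta_rows.append((c, None, None, role))
    counts = rng.poisson(rate, size=(n_otus, len(sample_ids)))
    counts *= rng.random((n_otus, len(sample_ids))) < 0.6  # sparsify
    frame = pd.DataFrame(
        counts.astype(np.int64),
        index=[f"OTU{o + 1:03d}" for o in range(n_otus)],
        columns=sample_ids,
    )
    meta = pd.DataFrame(
        meta_rows, columns=["sample_id", "site_id", "replicate_index", "role"]
    ).set_index("sample_id")
    return ReadCountMatrix(counts=frame, meta=meta)
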