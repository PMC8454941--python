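"""End-to-end orchestration: simulate/load -> filter -> score -> compare ->
predict, with one global seed fanned out into per-stage seeds and a single
machine-readable run report.

The report JSON is fully deterministic for a fixed seed; wall-clock
timings go to a separate sidecar so reports from identical runs stay
byte-identical.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Optional

import pandas as pd

from . import io as eio
from ._seeds import derive_seed
from .datamodel import FilterConfig, ReadCountMatrix, RunConfig
from .diversity import (
    composition_profiles,
    edna_site_richness,
    kicknet_site_richness,
    paired_richness_test,
    rank_concordance,
    richness_regression,
    richness_table,
)
from .errors import ValidationError
from .filtering import (
    apply_thresholds,
    collapse_replicates,
    compute_otu_thresholds,
    drop_weak_samples,
    restrict_to_indicators,
    restrict_to_phyla,
    stringency_profile,
)
from .forest import (
    RfConfig,
    build_presence_features,
    evaluate_predictions,
    predict_scores,
    tune_hyperparameters,
)
from .ibch import IbchConfig, load_ibch_config, score_communities
from .synthetic import generate_dataset, truth_summary

log = logging.getLogger(__name__)


def _reg_dict(reg) -> dict:
    return {
        "slope": reg.slope, "intercept": reg.intercept,
        "r_squared": reg.r_squared, "adj_r_squared": reg.adj_r_squared,
        "p_value": reg.p_value, "n": reg.n,
    }


def run_all(config: RunConfig) -> dict:
    """Execute all stages in order; returns the report dict.

    All stage outputs plus ``report.json`` and ``timings.json`` are written
    under ``config.outdir``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    report: dict = {"seed": config.seed,
                    "filter": {"k": config.filter.k, "n": config.filter.n,
                               "strategy": config.filter.threshold_strategy}}

    # ---- stage 1: inputs ------------------------------------------------
    t0 = time.perf_counter()
    truth = None
    if config.synthetic is not None:
        syn = config.synthetic
        if syn.seed is None:
            raise ValidationError("synthetic config must carry a seed")
        matrix, taxonomy, communities, truth = generate_dataset(syn)
        indicators = syn.indicators or eio.default_indicator_list()
        eio.write_count_matrix(matrix, outdir / "counts.tsv",
                               outdir / "sample_meta.tsv")
        eio.write_taxonomy(taxonomy, outdir / "taxonomy.tsv")
        eio.write_kicknet(communities, outdir / "kicknet.tsv")
        truth_summary(truth).to_csv(outdir / "truth.tsv", sep="\t")
    else:
        indicators = (
            eio.read_indicator_list(config.indicator_path)
            if config.indicator_path else eio.default_indicator_list()
        )
        matrix = eio.read_count_matrix(config.counts_path, config.meta_path)
        taxonomy = eio.read_taxonomy(config.taxonomy_path)
        communities = eio.read_kicknet(config.kicknet_path, indicators)
    ibch_cfg = (
        load_ibch_config(config.ibch_config_path, indicators)
        if config.ibch_config_path else IbchConfig(indicators=indicators)
    )
    report["inputs"] = {
        "n_otus": len(matrix.otu_ids),
        "n_samples": len(matrix.sample_ids),
        "n_field_samples": len(matrix.field_samples),
        "n_control_samples": len(matrix.control_samples),
        "n_sites_kicknet": len(communities),
        "n_indicator_taxa": len(indicators),
    }
    timings["inputs"] = time.perf_counter() - t0

    # ---- stage 2: filtering --------------------------------------------
    t0 = time.perf_counter()
    fc: FilterConfig = config.filter
    thresholds = compute_otu_thresholds(
        matrix, fc.threshold_strategy, fc.negatives_only
    )
    cleaned = apply_thresholds(matrix, thresholds)
    cleaned = drop_weak_samples(cleaned, fc.min_sample_depth)
    profile = stringency_profile(cleaned, fc.n)
    profile.to_csv(outdir / "stringency_profile.tsv", sep="\t", index=False)
    table = collapse_replicates(cleaned, fc)
    phyla_table = restrict_to_phyla(table, taxonomy)
    indicator_table = restrict_to_indicators(table, taxonomy, indicators)
    eio.write_site_detection_table(indicator_table,
                                   outdir / "site_indicator_reads.tsv")
    report["filtering"] = {
        "n_otus_in": len(matrix.otu_ids),
        "nonzero_thresholds": int((thresholds.values > 0).sum()),
        "n_sites": len(table.site_ids),
        "n_otus_detected": int(table.presence.any(axis=0).sum()),
        "n_otus_phyla": len(phyla_table.otu_ids),
        "n_otus_indicator": len(indicator_table.otu_ids),
        "stringency_profile": profile.to_dict("records"),
    }
    timings["filtering"] = time.perf_counter() - t0

    # ---- stage 3: biotic index from kick-net ---------------------------
    t0 = time.perf_counter()
    results = score_communities(communities, ibch_cfg)
    ibch_frame = pd.DataFrame([{
        "site_id": r.site_id, "richness": r.richness,
        "variety_class": r.variety_class,
        "indicator_group": r.indicator_group,
        "score": r.score, "category": r.category,
    } for r in results]).set_index("site_id").sort_index()
    ibch_frame.to_csv(outdir / "ibch_scores.tsv", sep="\t")
    report["ibch"] = {
        "n_sites": len(results),
        "mean_score": float(ibch_frame["score"].mean()),
        "min_score": int(ibch_frame["score"].min()),
        "max_score": int(ibch_frame["score"].max()),
        "categories": ibch_frame["category"]
        .value_counts().sort_index().to_dict(),
    }
    timings["ibch"] = time.perf_counter() - t0

    # ---- stage 4: diversity comparison ---------------------------------
    t0 = time.perf_counter()
    knet_rich = kicknet_site_richness(communities)
    edna_rich = edna_site_richness(indicator_table, taxonomy, indicators)
    rich = richness_table(knet_rich, edna_rich).sort_index()
    rich.to_csv(outdir / "richness.tsv", sep="\t")
    reg_ek = richness_regression(rich["kicknet_richness"],
                                 rich["edna_richness"])
    reg_ke = richness_regression(rich["edna_richness"],
                                 rich["kicknet_richness"])
    stat, pval = paired_richness_test(rich["kicknet_richness"],
                                      rich["edna_richness"])
    profiles = composition_profiles(indicator_table, communities, taxonomy,
                                    indicators)
    profiles.to_csv(outdir / "composition.tsv", sep="\t", index=False)
    _, rho = rank_concordance(profiles)
    report["diversity"] = {
        "mean_kicknet_richness": float(rich["kicknet_richness"].mean()),
        "mean_edna_richness": float(rich["edna_richness"].mean()),
        "richness_regression_edna_on_kicknet": _reg_dict(reg_ek),
        "richness_regression_kicknet_on_edna": _reg_dict(reg_ke),
        "paired_test": {"statistic": stat, "p_value": pval},
        "composition_spearman_rho": rho,
    }
    timings["diversity"] = time.perf_counter() - t0

    # ---- stage 5: taxonomy-free prediction -----------------------------
    t0 = time.perf_counter()
    features = build_presence_features(phyla_table).sort_index()
    observed = ibch_frame.loc[features.index, "score"].astype(float)
    rf_seed = derive_seed(config.seed, "forest")
    if config.rf_tune:
        rf_cfg = tune_hyperparameters(features, observed, seed=rf_seed,
                                      prediction_scheme=config.rf_scheme)
    else:
        rf_cfg = RfConfig(seed=rf_seed, prediction_scheme=config.rf_scheme)
    predicted = predict_scores(features, observed, rf_cfg)
    evaluation = evaluate_predictions(observed, predicted, ibch_cfg,
                                      site_ids=list(features.index))
    evaluation.per_site.rename_axis("site_id").to_csv(
        outdir / "predictions.tsv", sep="\t"
    )
    report["prediction"] = {
        "scheme": rf_cfg.prediction_scheme,
        "ntrees": rf_cfg.ntrees,
        "mtry": rf_cfg.resolved_mtry(features.shape[1]),
        "min_node_size": rf_cfg.min_node_size,
        "n_features": int(features.shape[1]),
        "regression_observed_on_predicted": _reg_dict(evaluation.regression),
        "kappa": evaluation.kappa,
        "kappa_band": evaluation.kappa_band,
        "pct_exact_category": evaluation.pct_exact,
        "pct_within_one_category": evaluation.pct_within_one,
        "deviation_histogram": {
            str(k): v for k, v in evaluation.deviation_histogram.items()
        },
    }
    timings["prediction"] = time.perf_counter() - t0

    (outdir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    (outdir / "timings.json").write_text(
        json.dumps(timings, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return report
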