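# ednaibch

Environmental-DNA metabarcoding is an attractive replacement for kick-net
sampling in routine river biomonitoring, but the two methods deliver
fundamentally different data: specimen counts of morphologically identified
indicator taxa on one side, read counts of sequence variants (OTUs) on the
other. `ednaibch` implements the full analysis chain needed to compare them
and to derive an ecological-state classification from eDNA alone:

1. **Cleaning** a replicated OTU × sample read table with control-based
   per-OTU thresholds and *k*-of-*n* replicate-consistency filters
   (default: detection in ≥ 2 of 4 filter replicates per site).
2. **Scoring** kick-net communities with the IBCH macroinvertebrate biotic
   index: richness of 145 pre-defined indicator taxa (mostly families;
   Porifera, Bryozoa and Cnidaria at phylum level) gives a variety class
   CV, the sensitivity value (GI, 1–9) of the best qualifying taxon gives
   an indicator group, and a lookup table maps (GI, CV) to a 0–20 score
   classified into five categories from "bad" to "very good".
3. **Comparing diversity**: per-site indicator richness of both methods
   (alpha), an OLS fit with adjusted R², a paired test for the systematic
   eDNA detection deficit, and pooled composition proportions per
   indicator group (gamma) with rank concordance.
4. **Predicting the index taxonomy-free**: because reads cannot be turned
   into specimen counts, a random-forest regressor learns the mapping from
   OTU presence/absence (all OTUs of the phyla Arthropoda, Cnidaria,
   Porifera, Bryozoa, Mollusca) to the kick-net-derived score — grid-tuned
   around mtry = n/3, node size 3, 500 trees — with strictly out-of-sample
   per-site predictions (leave-one-out, or out-of-bag). Agreement is
   quantified by the adjusted R² of observed ~ predicted, Cohen's κ on the
   five categories, and the signed category-deviation histogram.
5. **Simulating** paired datasets from a latent site-quality model so every
   stage is testable with known ground truth (92 sites × 4 replicates by
   default, heavy non-target OTU load, low-level control contamination).

It is intended for researchers and monitoring practitioners analysing
replicated COI metabarcoding data against an indicator-based assessment
framework.

## Worked example

Scoring a kick-net community (`python examples/score_kicknet.py`):

```
site             : demo-site
indicator richness: 9 taxa -> variety class CV 3
indicator group  : GI 9 (most sensitive taxon meeting its abundance minimum)
IBCH score       : 11 / 20
ecological state : moderate
without Perlidae : score 6 (loss of the most sensitive family lowers the state)
```

Nine indicator taxa fall in variety class 3; the four Perlidae specimens
meet that family's abundance minimum, so the indicator group is 9 and the
default table yields score min(9 + 3 − 1, 20) = 11 ("moderate"). Dropping
the single sensitive family collapses GI to 5 and the score to 6 — the
index is driven by the most pollution-intolerant taxon present.

Predicting the index from eDNA on a 40-site synthetic dataset
(`python examples/predict_index.py`):

```
features: 571 OTU presence columns, 40 sites, leave-one-out forest
observed ~ predicted: adj R^2 = 0.32, p = 8.6e-05
Cohen's kappa = 0.37 (poor)
65% of sites in the same state category, 100% within one category
```

Even with a modest continuous fit, almost two thirds of the sites land in
the same ecological-state category as the kick-net assessment and none is
off by more than one category. The other examples
(`simulate_and_filter.py`, `compare_diversity.py`) walk through the
cleaning cascade and the alpha/gamma diversity comparison.

A thin CLI wraps the same functions (`ednaibch simulate | filter | ibch |
diversity | predict | run-all`); `run-all --seed 7 --outdir out/` executes
the whole chain and writes a deterministic `report.json`.

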