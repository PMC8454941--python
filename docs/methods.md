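# Methods

This note documents the models and procedures implemented in `ednaibch`,
the defaults chosen where the underlying monitoring framework leaves room,
and what the synthetic-data tests do and do not establish.

## Cleaning cascade

The pipeline starts from an OTU × sample integer read table with four
field filter replicates per site plus negative and positive controls.

**Control-based thresholds.** Two strategies are implemented because the
control rule of record can be read in two ways:

- `max_in_controls` (default): for each OTU, the maximum read count over
  all control samples is subtracted from every field sample (floored at
  zero). This is the subtraction reading and treats control reads as an
  additive contamination level.
- `proportional`: for each OTU, the fraction of its total reads observed
  in controls defines a per-sample minimum (fraction × sample depth);
  counts below it are removed. This is the detection-minimum reading.

Positive controls contribute to thresholds alongside negatives by default
(`negatives_only` restricts to negatives). Control columns are zeroed
after use. Neither strategy can increase a count, so cleaning is
monotone.

**Replicate consistency.** An OTU is detected at a site when it has
nonzero (post-threshold) reads in at least *k* of the *n* replicates
(default 2 of 4). Pooled site reads are the sum over the site's
replicates (mean pooling available, ceiling-rounded to keep "present ⇔
pooled > 0"). Detection sets are nested in *k* by construction, which the
tests verify by brute force. Sites with fewer than *k* replicates are
excluded with a warning rather than rescaling *k*, matching the fixed
n = 4 design. An optional minimum per-sample read depth (default 0 = off)
removes weak samples before collapsing.

**Taxonomic restriction.** For diversity comparisons the table is
restricted to OTUs linked to one of the 145 indicator taxa; for the
taxonomy-free prediction it is restricted to all OTUs of the five
surveyed phyla (Arthropoda, Cnidaria, Porifera, Bryozoa, Mollusca),
which retains molecular diversity that the indicator list ignores. The
indicator restriction is applied to the full detection table, not to the
phylum subset, because a few indicator groups (oligochaetes, leeches,
flatworms) belong to other phyla.

## The biotic index engine

The IBCH index is computed from kick-net specimen counts in three steps:
variety class CV ∈ 1..14 from indicator richness; indicator group
GI ∈ 1..9 as the maximum sensitivity value over taxa meeting their
per-taxon minimum abundance; score = table[GI, CV] ∈ 0..20, classified
into five categories. Richness 0 or no qualifying taxon gives score 0.

The official lookup table, variety bins, GI values and abundance minima
are distributed with the national method, not in the open literature, so
the packaged defaults are structural surrogates, shipped as editable
config:

- variety bins: CV = ⌈richness / 4⌉ capped at 14 (uniform width);
- score table: min(GI + CV − 1, 20), which is non-decreasing in both
  arguments and reaches the documented ceiling of 20;
- GI values per family: conventional sensitivity ordering of the
  IBGN-family tradition (stonefly families high, chironomids and worms
  low); abundance minimum 3 specimens for GI ≥ 5, else 1;
- categories: equal-width quintiles 0–4 "bad", 5–8 "unsatisfactory",
  9–12 "moderate", 13–16 "good", 17–20 "very good".

All four can be replaced via `IbchConfig` / YAML without code changes.
The engine validates monotonicity and partition properties at load time.
The index scale is stated as 0–20 in the method description and 5–20 in
some published figures; the engine supports either via the category
bounds and score table and does not resolve the discrepancy.

eDNA data never enter the index engine directly: read counts are not
specimen counts. The eDNA route to the index is exclusively the
random-forest prediction.

## Diversity comparison

Alpha: per-site distinct indicator taxa (OTU multiplicity collapses to
taxa). The linear richness model is reported in both directions (eDNA on
kick-net and the reverse) with adjusted R² = 1 − (1 − R²)(n − 1)/(n − 2).
The detection deficit is tested with a two-sided paired t-test by default
(Wilcoxon signed-rank optional); the choice is a default, not a claim
about the original analysis, which does not name its test. Gamma:
proportions per indicator higher-group are computed over all sites pooled
— eDNA as group reads / total indicator reads, kick-net as group
specimens / total specimens — so each method's proportions sum to 1;
rank agreement is summarised by dense ranks and tie-corrected Spearman ρ.
Using total reads (rather than total indicator reads) in the eDNA
denominator is available behind a flag but then proportions no longer
sum to one.

## Taxonomy-free prediction

Features are binary site × OTU detections after phylum restriction;
zero-variance columns are dropped. The regressor is a random forest
(scikit-learn) with the canonical defaults mtry = ⌊n_features/3⌋,
minimum node size 3, 500 trees. The grid search (5-fold seeded CV RMSE)
covers mtry ∈ {n/5, n/3, n/2}, node size ∈ {3, 5, 10}, ntrees ∈ {500};
ties break toward the cheaper model. "Predicted for every sample
iteratively" is implemented as leave-one-out refits (default, strictly
out-of-sample) with out-of-bag prediction as a faster alternative; both
are regression forests whose continuous predictions are rounded half-up
before categorisation. Whether the original grid search used CV or OOB
error is unstated; 5-fold CV was chosen here.

Evaluation regresses observed on predicted (the reverse direction is a
one-line change and is reported by the diversity module for richness),
computes unweighted Cohen's κ on the five categories (a linear-weighted
variant exists behind a flag), maps κ to the conventional verbal bands
(boundaries fall to the lower band), and tabulates the signed category
deviation. Forest predictions are averages of observed responses, so they
can never leave the observed score range — predictions are compressed
toward the centre, which is visible in the category histograms.

## Synthetic data generator

Each site carries a latent quality q ~ truncated Normal(13.3, 2) on
[0, 20] — the scale and centre of realized index scores in Swiss rivers.
Each indicator taxon j has a sensitivity threshold
t_j = 16.7 + 1.5·gi_j + Normal(0, 6), and occurs at site i with
probability logistic(q_i − t_j). The constants were calibrated once,
analytically, so that mean kick-net indicator richness lands near 23
with a range of roughly 10–45 under the default design, and sensitive
taxa are rare — both properties of the field campaign the generator
emulates. Kick-net observation thins occurrences at detection
probability 0.9 and draws specimen counts from a shifted negative
binomial (1 + NB, mean ≈ 13.5).

On the molecular side each taxon spawns 1–5 OTUs (uniform). Its dominant
OTU is locally present wherever the taxon occurs; additional OTUs are
present with probability 0.2 (distinct lineages do not co-occur
everywhere). Present OTUs are detected per filter replicate with
probability 0.45, independently across replicates; 1500 non-target OTUs
(rotifers and other bycatch, ~30 % of them in the five surveyed phyla)
are present per site with probability 0.3. Replicate read counts fill a
log-normal per-sample depth (mean 20 000, a scaled-down sequencing depth)
by a multinomial over the detected OTUs with log-normal site-level
abundance weights; indicator OTUs get a 4× weight boost so they sit in
the upper read ranks. Every detected OTU receives at least one read and
column sums equal the drawn depth exactly. Controls receive contamination
in a ~2 % random subset of OTUs at counts capped at 1 % of the OTU's mean
field count (abundance-weighted contamination is a config switch).

Under these defaults the per-taxon eDNA capture probability after 2-of-4
filtering is ≈ 0.7 versus 0.9 for kick-net, so eDNA detects
significantly fewer indicator taxa per site — the direction of the
documented field bias. Reproducing the full magnitude of that gap
(23 vs 9 taxa) would require a per-replicate detection probability near
0.2; the default keeps the stated 0.45 and asserts direction, not
magnitude.

**What the generator does not emulate.** A single latent variable drives
both data types, so kick-net and eDNA richness are strongly correlated
across sites — unlike the field data, where local richness patterns of
the two methods largely decorrelate (DNA transport, primer bias,
patchiness). Passing recovery tests therefore shows that the pipeline
extracts a signal that is present; it does not show how strong that
signal is in real rivers. There is no spatial/hydrological transport
model, no PCR or chimera simulation, no sequence-level output, and
replicate detections are conditionally independent given occurrence.

## Numerical and reproducibility choices

One global seed fans out to per-stage seeds by hashing stage labels
(SHA-256, 31-bit), so stages re-run in isolation match full-run results;
leave-one-out refits get per-site derived seeds. Run reports are
deterministic JSON; wall-clock timings are written to a separate sidecar
so identical runs are byte-identical. Degenerate cases are defined
explicitly: all-zero paired differences report p = 1 with a warning;
κ with degenerate marginals (p_e = 1) is 1 when agreement is perfect,
else 0, with a warning; constant forest predictions yield a flagged
zero-R² regression summary. Missing TSV cells are errors, never zeros.
Score rounding before categorisation is half-up.

Test and acceptance problem sizes (92 sites for full-scale checks,
15–40 sites for unit-level ones) were chosen to exercise the default
study design while keeping the whole suite in the minutes range on one
CPU.

## Known limitations

- Default index tables are structural surrogates; regulatory use requires
  loading the official national tables.
- The richness-decorrelation aspect of real paired data is not emulated
  (see above), so cross-method richness R² on synthetic data is high
  rather than near zero.
- The classification-forest variant, variable-importance-based discovery
  of new indicator taxa, and other biotic indices are out of scope.
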