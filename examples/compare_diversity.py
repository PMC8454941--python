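"""Alpha- and gamma-diversity comparison between kick-net and eDNA.

Per-site indicator richness differs systematically (eDNA detects fewer
taxa locally), while the pooled composition of indicator groups is similar
for common groups -- the pattern the pipeline is built to quantify.
"""

from ednaibch import (
    FilterConfig,
    SyntheticConfig,
    apply_thresholds,
    collapse_replicates,
    composition_profiles,
    compute_otu_thresholds,
    default_indicator_list,
    edna_site_richness,
    generate_dataset,
    kicknet_site_richness,
    paired_richness_test,
    rank_concordance,
    restrict_to_indicators,
)

ind = default_indicator_list()
cfg = SyntheticConfig(seed=7, n_sites=40, read_depth_mean=8000.0)
matrix, taxonomy, communities, _ = generate_dataset(cfg)

cleaned = apply_thresholds(matrix, compute_otu_thresholds(matrix))
table = collapse_replicates(cleaned, FilterConfig(k=2, n=4))
indicator_table = restrict_to_indicators(table, taxonomy, ind)

kick = kicknet_site_richness(communities)
edna = edna_site_richness(indicator_table, taxonomy, ind)
stat, p = paired_richness_test(kick.loc[edna.index], edna)
print(f"mean indicator richness: kick-net {kick.mean():.1f}, "
      f"eDNA {edna.mean():.1f}")
print(f"paired t-test (kick-net - eDNA): t = {stat:.1f}, p = {p:.2e}")
print("-> eDNA detects significantly fewer indicator taxa per site\n")

profiles = composition_profiles(indicator_table, communities, taxonomy, ind)
ranks, rho = rank_concordance(profiles)
top = profiles[profiles["rank"] <= 3].sort_values(["method", "rank"])
print("top indicator groups by pooled proportion:")
print(top.to_string(index=False))
print(f"\nSpearman rank concordance across all groups: rho = {rho:.2f}")
print("-> overall (gamma) composition agrees despite the local deficit")
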