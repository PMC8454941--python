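"""Score a kick-net community with the IBCH biotic index.

The index combines the variety class CV (richness bin) with the indicator
group GI (sensitivity of the best qualifying taxon) via a lookup table on
the 0-20 scale, then maps the score to one of five ecological-state
categories.
"""

from ednaibch import IbchConfig, KicknetCommunity, ibch_score

community = KicknetCommunity("demo-site", {
    "Perlidae": 4,        # stonefly family, high sensitivity (GI 9)
    "Heptageniidae": 12,  # mayfly family, GI 5
    "Baetidae": 55,       # tolerant mayflies, GI 2
    "Gammaridae": 130,
    "Chironomidae": 210,
    "Simuliidae": 40,
    "Hydropsychidae": 18,
    "Elmidae": 6,
    "Asellidae": 3,
})

result = ibch_score(community, IbchConfig())
print(f"site             : {result.site_id}")
print(f"indicator richness: {result.richness} taxa -> variety class "
      f"CV {result.variety_class}")
print(f"indicator group  : GI {result.indicator_group} "
      "(most sensitive taxon meeting its abundance minimum)")
print(f"IBCH score       : {result.score} / 20")
print(f"ecological state : {result.category}")
# Removing the 4 Perlidae would drop GI to 5 and the score with it:
without = KicknetCommunity("demo-site", {
    t: c for t, c in community.counts.items() if t != "Perlidae"
})
print(f"without Perlidae : score {ibch_score(without, IbchConfig()).score} "
      "(loss of the most sensitive family lowers the state)")
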