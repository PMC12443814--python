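parameter,overall,rainy,dry
bird_richness,18,17,18
plant_richness,14,9,11
n_links,110,77,85
interaction_frequency,4446,2323,2123
z_connectance,-24.86,-15.65,-17.54
z_wnodf,-1.34,-0.280,-2.59
z_h2prime,75.39,47.70,40.31
z_modularity,35.85,25.01,23.04
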