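scope,target,coverage_pct
overall,interactions,99.74
overall,birds,99.48
overall,plants,99.17
rainy,interactions,99.83
rainy,birds,99.35
rainy,plants,99.66
dry,interactions,99.82
dry,birds,99.76
dry,plants,98.26
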