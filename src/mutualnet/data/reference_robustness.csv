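removed_side,scenario,R
birds,degree_desc,0.459
birds,random,0.845
birds,degree_asc,0.936
plants,degree_desc,0.404
plants,random,0.689
plants,degree_asc,0.872
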