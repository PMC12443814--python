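code,species,role,degree,strength,specialization
B1,Pycnonotus jocosus,bird,14,7.527,0.048
B2,Pycnonotus aurigaster,bird,14,2.241,0.037
B3,Pycnonotus sinensis,bird,14,1.557,0.013
B4,Pycnonotus xanthorrhous,bird,11,0.668,0.040
B5,Phylloscopus inornatus,bird,10,0.432,0.069
B6,Zosterops japonicus,bird,11,0.547,0.124
B7,Orthotomus sutorius,bird,8,0.374,0.160
B8,Spilopelia chinensis,bird,4,0.173,0.292
B9,Copsychus saularis,bird,3,0.081,0.228
B10,Lonchura punctulata,bird,2,0.056,0.221
B11,Passer montanus,bird,3,0.052,0.178
B12,Turdus merula,bird,3,0.043,0.143
B13,Spizixos semitorques,bird,2,0.049,0.250
B14,Spodiopsar cineraceus,bird,1,0.045,0.378
B15,Acridotheres cristatellus,bird,1,0.070,0.470
B16,Spodiopsar sericeus,bird,4,0.037,0.144
B17,Dicaeum cruentatum,bird,3,0.026,0.214
B18,Lonchura striata,bird,2,0.022,0.206
P1,Ficus concinna,plant,14,6.802,0.093
P2,Camphora officinarum,plant,11,4.149,0.167
P3,Ficus altissima,plant,16,2.653,0.024
P4,Melia azedarach,plant,7,1.474,0.108
P5,Flueggea virosa,plant,9,0.838,0.068
P6,Bischofia javanica,plant,7,0.586,0.053
P7,Phyllanthus reticulatus,plant,6,0.494,0.106
P8,Ficus tinctoria,plant,5,0.119,0.108
P9,Broussonetia papyrifera,plant,8,0.231,0.077
P10,Causonis japonica,plant,6,0.189,0.050
P11,Maclura tricuspidata,plant,6,0.224,0.070
P12,Syzygium cumini,plant,5,0.100,0.106
P13,Persicaria chinensis,plant,6,0.105,0.059
P14,Sageretia thea,plant,4,0.038,0.068
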