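chemical,css_uM_per_mgkgday,exposure_mgkgday,pod_rfd_mgkgday
Cadmium chloride,8.5,0.0005,0.005
Mercuric chloride,12.0,0.0002,0.003
Potassium chromate (VI),6.0,0.0003,0.009
Cobalt chloride,4.2,0.0004,0.03
Zinc chloride,3.1,0.002,0.3
Naphthalene,0.9,0.0008,0.2
Fluoranthene,1.4,0.0001,0.4
"p,p'-DDT",2.6,0.00005,0.05
Dieldrin,3.8,0.00002,0.005
Heptachlor,2.2,0.00001,0.015
Lindane,1.8,0.00004,0.08
Chlorpyrifos,1.1,0.0002,0.03
Diazinon,0.8,0.0001,0.07
Pentachlorophenol,2.9,0.00008,0.1
"2,4-dinitrophenol",1.6,0.00006,0.06
Dibutyl phthalate,0.7,0.001,0.6
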