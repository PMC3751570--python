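region_id,name,weight_fraction,views
1,skull,0.118,anterior+posterior
2,cervical_spine,0.015,anterior+posterior
3,thoracic_spine,0.070,anterior+posterior
4,lumbar_spine,0.055,anterior+posterior
5,ribs_sternum,0.110,anterior+posterior
6,scapulae_clavicles,0.055,anterior+posterior
7,pelvis_sacrum,0.170,anterior+posterior
8,humeri,0.060,anterior+posterior
9,femora,0.160,anterior+posterior
10,tibiae_fibulae,0.120,anterior+posterior
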