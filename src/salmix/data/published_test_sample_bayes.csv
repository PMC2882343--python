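test_sample,allocation_river,assignment_river,allocation_pooled_river,assignment_pooled_river,allocation_region,assignment_region
Lune(2005-05),15.751,13.725,74.391,88.235,92.32,100.0
Ribble(2004),56.282,74.0,66.488,76.0,93.389,100.0
Dee(1984-88),3.563,2.041,45.607,46.0,77.427,87.76
Tamar(1987),95.07,100.0,84.513,90.0,96.356,100.0
Mudeford(2006),97.601,100.0,97.527,100.0,97.802,100.0
Aven+(2005),87.172,91.892,86.438,91.892,96.347,100.0
Narcea(2006),83.287,87.387,85.819,91.892,99.068,100.0
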