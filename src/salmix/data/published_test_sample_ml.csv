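test_sample,capture_method,n,allocation_river,assignment_river,allocation_pooled_river,assignment_pooled_river,allocation_region,assignment_region
Lune(2004-05),Estuary Net,49,26.7,28.57,49.41,53.01,77.72,81.63
Ribble2004,Estuary Net,50,20.96,22.0,37.94,40.0,80.39,82.0
Dee(1984-88),Estuary Net,47,8.3,8.51,15.02,17.02,34.81,34.04
Tamar1987,Estuary Net,62,41.66,41.94,57.08,65.08,77.22,80.65
Mudeford2006,Estuary Net,47,81.24,93.3,88.5,89.36,98.47,97.87
Aven+2005,Rod Caught,37,42.78,40.54,43.12,40.54,92.0,91.89
Narcea2006,Rod Caught,112,37.25,39.29,28.73,28.57,97.04,96.43
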