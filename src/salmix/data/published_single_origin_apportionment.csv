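catchment,sample,n,sample_allocation_10loci,sample_allocation_12loci,catchment_allocation,pooled_catchment_allocation,regional_allocation
ANNAN,ANN.Bk,30,0.5791,0.5541,0.5908,,0.7673
ANNAN,ANN.Ev,35,0.2918,0.3317,0.4073,0.5682,0.8931
ANNAN,ANN.Whi,31,0.2939,0.321,0.4062,,0.7882
AULNE,AULNE,39,0.3475,0.4081,0.4081,0.3932,0.8717
AVON,AVON.Brd,23,0.7956,0.8068,0.959,0.983,0.9993
AVON,AVON.Bug,20,0.604,0.6657,0.9042,,0.9935
AWE,AWE.Bra,35,0.9551,0.9673,0.9703,,0.9751
AWE,AWE.Cla,35,0.9203,0.9553,0.9575,0.9516,0.9619
AWE,AWE.Mai,35,0.8611,0.8929,0.8953,,0.9127
AYR,AYR.Gle,30,0.4368,0.4197,0.9756,,0.9786
AYR,AYR.How,30,0.3265,0.4122,0.7047,0.9524,0.7748
AYR,AYR.Lug,68,0.7924,0.8418,0.9173,,0.9381
BARROW,BAR.Bal,40,0.5409,0.5224,0.5224,0.4629,0.7475
BLAVET,BLAVET,49,0.3544,0.5474,0.5474,0.5415,0.9445
BLACKWATER,ROAG.Tar,33,0.498,0.5202,0.5202,0.4621,0.729
BOYNE,BOY.Dee,36,0.7222,0.7764,0.8785,,0.907
BOYNE,BOY.Moy,35,0.6724,0.7129,0.8041,0.9169,0.8372
BOYNE,BOY.Ska,35,0.5359,0.6703,0.7859,,0.8135
CAMAL,CAM.Del,30,0.4496,0.528,0.5735,,0.8119
CAMAL,CAM.Gam,30,0.5369,0.6511,0.6977,0.7511,0.8668
CAMAL,CAM.Ken,30,0.3952,0.427,0.5024,,0.8318
CARES,CARES02,72,0.6363,0.6855,0.6866,0.7858,0.9831
CARES,CAR.Cas,24,0.914,0.9113,0.9692,,0.9981
CLYDE,CLY.Boc,30,0.4885,0.5693,0.5712,0.716,0.6497
CLYDE,CLY.Cal,25,0.7475,0.7987,0.8014,,0.8456
CORK BLACKWATER,COR.Awn,35,0.3076,0.3599,0.6915,,0.7493
CORK BLACKWATER,COR.Cly,35,0.3581,0.3624,0.6443,0.764,0.7193
CORK BLACKWATER,COR.Gle,35,0.2661,0.3763,0.5453,,0.5836
CREE,CREE.Whi,39,0.4748,0.5826,0.5826,0.5111,0.6371
CREED,CREED.All,36,0.6212,0.6257,0.6257,0.5744,0.753
DART,DAR.Pos,84,0.9141,0.9423,0.9423,0.9375,0.9793
DEE,DEE.Abb,24,0.4976,0.5313,0.5701,0.718,0.7101
DEE,DEE.Cer,39,0.6529,0.654,0.6593,,0.7393
DERWENT,DERW.Dash,25,0.0444,0.0916,0.2118,,0.4926
DERWENT,DERW.Mar,30,0.223,0.2617,0.402,0.6065,0.6299
DERWENT,DERW.New,32,0.4599,0.455,0.5733,,0.6801
DOON,DOON.Muc,30,0.6977,0.6867,0.7515,,0.7861
DOON,DOON.Nes,27,0.5924,0.5767,0.7433,0.7978,0.7612
DOON,DOON.Ske,29,0.2733,0.3583,0.4359,,0.5441
EDEN,EDEN.Dac,30,0.5034,0.5582,0.7146,,0.9642
EDEN,EDEN.Sca,31,0.5468,0.4726,0.5167,0.7984,0.8917
EDEN,EDEN.Swin,30,0.454,0.586,0.72,,0.9156
ELLE,ELLE,50,0.369,0.4589,0.4589,0.4562,0.9604
ELORN,ELORN,49,0.5774,0.6068,0.6068,0.6152,0.9809
EO,EO,46,0.9593,0.9704,0.9704,0.9714,0.9897
ESK (Border),ESKB.Boy,30,0.1651,0.2192,0.3084,,0.7579
ESK (Border),ESKB.Ewe,30,0.1758,0.1523,0.2305,0.56,0.7846
ESK (Border),ESKB.Lid,35,0.6293,0.6615,0.6958,,0.9187
EWE,EWE.Gru,26,0.3999,0.4459,0.4479,0.6913,0.8044
EWE,EWE.Kem,23,0.6749,0.7443,0.751,,0.856
EXE,EXE.Dan,43,0.7485,0.7621,0.9266,,0.9808
EXE,EXE.Sher,31,0.376,0.4859,0.7901,0.9017,0.9325
EXE,EXE.Sim,68,0.7348,0.8304,0.872,,0.9513
FLEET,FLE.Big,21,0.212,0.3837,0.4322,0.7521,0.567
FLEET,FLE.Lit,26,0.7316,0.7677,0.8106,,0.8337
FOWEY,FOW.Mar,20,0.5447,0.6016,0.6146,0.6367,0.8273
FOWEY,FOW.Tre,36,0.5255,0.5423,0.5448,,0.8574
GRUINARD,GRU.Abh,27,0.1807,0.27,0.2859,0.6262,0.6265
GRUINARD,GRU.Ghi,27,0.5741,0.5889,0.645,,0.7815
ITCHEN,ITC.Bis,53,0.9215,0.9644,0.9644,0.9608,0.9975
KENT,KENT.SpA,41,0.5339,0.5975,0.6246,0.5048,0.8821
KENT,KENT.Sto,20,0.0645,0.0499,0.2331,,0.7921
LAUNE,LAU.Cot,47,0.5335,0.6026,0.6026,0.5624,0.7022
LAXFORD,LAX.Ach,32,0.654,0.6882,0.7423,,0.8579
LAXFORD,LAX.Mai,30,0.2647,0.3172,0.3582,0.8735,0.6014
LAXFORD,LAX.Thu,32,0.9983,0.9978,0.9978,,0.9986
LEUGER,LEUGER,48,0.5531,0.6086,0.6086,0.6205,0.9235
LOCH LOCHY,LOC.loc,46,0.5521,0.6493,0.6621,0.729,0.7789
LOCH LOCHY,LOC.lun,26,0.4907,0.4937,0.6243,,0.7567
LOCH,LOM.End,25,0.7578,0.8568,0.9377,0.9631,0.9478
LOMOND,LOM.Fru,51,0.9356,0.9613,0.9639,,0.9712
LUNE,LUNE.Birk,29,0.2499,0.3227,0.4072,,0.7938
LUNE,LUNE.Cha,28,0.3762,0.3617,0.4067,0.6959,0.824
LUNE,LUNE.Ger,30,0.5511,0.627,0.7186,,0.9407
MOY,MOY.TriL,42,0.6995,0.7281,0.7281,0.6681,0.8209
NARCEA,NARCEA02,40,0.5757,0.6291,0.6291,0.5309,0.9872
NITH,NITH.RC,30,0.2519,0.2875,0.3588,,0.859
NITH,NITH.NM,30,0.1596,0.1928,0.2553,0.4859,0.7314
NITH,NITH.NSC,30,0.619,0.6766,0.6994,,0.9542
RIBBLE,RIB.Bro,28,0.3664,0.3255,0.4399,,0.6874
RIBBLE,RIB.Cra,29,0.5675,0.5534,0.701,0.7816,0.9421
RIBBLE,RIB.Ham,31,0.54,0.5979,0.7223,,0.9008
SCORFF,SCORFF,47,0.4018,0.5002,0.5002,0.5077,0.9778
SEE,SEE,49,0.5916,0.6705,0.6705,0.6607,0.9613
SELLA,SELLA.Pig,34,0.6253,0.6967,0.7406,0.663,0.9934
SELLA,SELLA02,48,0.3433,0.4001,0.4048,,0.9727
SELUNE,SELUNE,50,0.5384,0.6437,0.6437,0.6398,0.9437
SEVERN,SEV.CinA,22,0.5538,0.5591,0.5591,0.4827,0.9147
SUIR,SUIR.Clo,28,0.2048,0.1644,0.249,0.5407,0.5215
SUIR,SUIR.MCb,20,0.2218,0.2102,0.6235,,0.8203
TAMAR,TAM.Gat,33,0.3341,0.3357,0.5546,,0.8327
TAMAR,TAM.Ott,33,0.4564,0.4843,0.6979,0.811,0.8377
TAMAR,TAM.Tre,30,0.6582,0.6171,0.7382,,0.8688
TAW,TAW.Bra,25,0.5186,0.6695,0.6897,0.5992,0.9141
TAW,TAW.Twi,32,0.3199,0.4196,0.4226,,0.8506
TEIFI,TEIFI.Cle,27,0.2314,0.2581,0.4018,,0.6037
TEIFI,TEIFI.Egn,24,0.3088,0.4052,0.6015,0.6292,0.8136
TEIFI,TEIFI.Lam,27,0.2229,0.231,0.4185,,0.7051
TEST,TEST,49,0.8644,0.9642,0.9642,0.9676,0.9962
TORRIDGE,TOR.Eoak,21,0.2131,0.3046,0.3064,0.8098,0.7273
TORRIDGE,TOR.Woak,29,0.9248,0.9362,0.9384,,0.9765
ULLA,ULLA,46,0.935,0.9641,0.9641,0.961,0.9996
USK,USK.Bra,29,0.1643,0.216,0.6023,,0.8644
USK,USK.Gir,30,0.184,0.2293,0.66,0.7371,0.8865
USK,USK.Grw,29,0.3297,0.2726,0.6865,,0.9321
WYE,WYE.Lly(Wye),30,0.4398,0.4951,0.7486,,0.9671
WYE,WYE.Edw,30,0.229,0.3178,0.5506,0.7413,0.9389
WYE,WYE.Gar.,27,0.1242,0.1532,0.3548,,0.928
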