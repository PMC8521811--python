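sex,agemos,L,M,S
male,144,-2.20000,17.80000,0.13000
male,145,-2.19375,17.84743,0.13012
male,146,-2.18750,17.89494,0.13025
male,147,-2.18125,17.94253,0.13037
male,148,-2.17500,17.99019,0.13050
male,149,-2.16875,18.03793,0.13062
male,150,-2.16250,18.08574,0.13075
male,151,-2.15625,18.13363,0.13087
male,152,-2.15000,18.18160,0.13100
male,153,-2.14375,18.22964,0.13112
male,154,-2.13750,18.27776,0.13125
male,155,-2.13125,18.32595,0.13137
male,156,-2.12500,18.37422,0.13150
male,157,-2.11875,18.42256,0.13162
male,158,-2.11250,18.47099,0.13175
male,159,-2.10625,18.51948,0.13187
male,160,-2.10000,18.56806,0.13200
male,161,-2.09375,18.61670,0.13212
male,162,-2.08750,18.66543,0.13225
male,163,-2.08125,18.71423,0.13237
male,164,-2.07500,18.76311,0.13250
male,165,-2.06875,18.81206,0.13262
male,166,-2.06250,18.86109,0.13275
male,167,-2.05625,18.91019,0.13287
male,168,-2.05000,18.95937,0.13300
male,169,-2.04375,19.00863,0.13312
male,170,-2.03750,19.05796,0.13325
male,171,-2.03125,19.10737,0.13337
male,172,-2.02500,19.15686,0.13350
male,173,-2.01875,19.20642,0.13362
male,174,-2.01250,19.25605,0.13375
male,175,-2.00625,19.30577,0.13387
male,176,-2.00000,19.35556,0.13400
male,177,-1.99375,19.40542,0.13412
male,178,-1.98750,19.45536,0.13425
male,179,-1.98125,19.50538,0.13437
male,180,-1.97500,19.55547,0.13450
male,181,-1.96875,19.60564,0.13462
male,182,-1.96250,19.65588,0.13475
male,183,-1.95625,19.70620,0.13487
male,184,-1.95000,19.75660,0.13500
male,185,-1.94375,19.80707,0.13512
male,186,-1.93750,19.85762,0.13525
male,187,-1.93125,19.90824,0.13537
male,188,-1.92500,19.95894,0.13550
male,189,-1.91875,20.00972,0.13562
male,190,-1.91250,20.06057,0.13575
male,191,-1.90625,20.11150,0.13587
male,192,-1.90000,20.16250,0.13600
male,193,-1.89375,20.21358,0.13612
male,194,-1.88750,20.26474,0.13625
male,195,-1.88125,20.31597,0.13637
male,196,-1.87500,20.36727,0.13650
male,197,-1.86875,20.41866,0.13662
male,198,-1.86250,20.47012,0.13675
male,199,-1.85625,20.52165,0.13687
male,200,-1.85000,20.57326,0.13700
male,201,-1.84375,20.62495,0.13712
male,202,-1.83750,20.67671,0.13725
male,203,-1.83125,20.72855,0.13737
male,204,-1.82500,20.78047,0.13750
male,205,-1.81875,20.83246,0.13762
male,206,-1.81250,20.88453,0.13775
male,207,-1.80625,20.93667,0.13787
male,208,-1.80000,20.98889,0.13800
male,209,-1.79375,21.04118,0.13812
male,210,-1.78750,21.09355,0.13825
male,211,-1.78125,21.14600,0.13837
male,212,-1.77500,21.19852,0.13850
male,213,-1.76875,21.25112,0.13862
male,214,-1.76250,21.30380,0.13875
male,215,-1.75625,21.35655,0.13887
male,216,-1.75000,21.40938,0.13900
male,217,-1.74375,21.46228,0.13912
male,218,-1.73750,21.51526,0.13925
male,219,-1.73125,21.56831,0.13937
male,220,-1.72500,21.62144,0.13950
male,221,-1.71875,21.67465,0.13962
male,222,-1.71250,21.72793,0.13975
male,223,-1.70625,21.78129,0.13987
male,224,-1.70000,21.83472,0.14000
male,225,-1.69375,21.88823,0.14012
male,226,-1.68750,21.94182,0.14025
male,227,-1.68125,21.99548,0.14037
male,228,-1.67500,22.04922,0.14050
male,229,-1.66875,22.10303,0.14062
male,230,-1.66250,22.15692,0.14075
male,231,-1.65625,22.21089,0.14088
male,232,-1.65000,22.26493,0.14100
male,233,-1.64375,22.31905,0.14113
male,234,-1.63750,22.37324,0.14125
male,235,-1.63125,22.42751,0.14138
male,236,-1.62500,22.48186,0.14150
male,237,-1.61875,22.53628,0.14163
male,238,-1.61250,22.59078,0.14175
male,239,-1.60625,22.64535,0.14187
male,240,-1.60000,22.70000,0.14200
female,144,-2.25000,18.30000,0.13600
female,145,-2.23906,18.32975,0.13612
female,146,-2.22812,18.35961,0.13625
female,147,-2.21719,18.38960,0.13637
female,148,-2.20625,18.41970,0.13650
female,149,-2.19531,18.44993,0.13662
female,150,-2.18438,18.48027,0.13675
female,151,-2.17344,18.51074,0.13687
female,152,-2.16250,18.54132,0.13700
female,153,-2.15156,18.57202,0.13712
female,154,-2.14062,18.60284,0.13725
female,155,-2.12969,18.63378,0.13737
female,156,-2.11875,18.66484,0.13750
female,157,-2.10781,18.69602,0.13762
female,158,-2.09687,18.72732,0.13775
female,159,-2.08594,18.75874,0.13787
female,160,-2.07500,18.79028,0.13800
female,161,-2.06406,18.82193,0.13812
female,162,-2.05313,18.85371,0.13825
female,163,-2.04219,18.88561,0.13837
female,164,-2.03125,18.91762,0.13850
female,165,-2.02031,18.94976,0.13862
female,166,-2.00937,18.98201,0.13875
female,167,-1.99844,19.01438,0.13887
female,168,-1.98750,19.04688,0.13900
female,169,-1.97656,19.07949,0.13912
female,170,-1.96562,19.11222,0.13925
female,171,-1.95469,19.14507,0.13937
female,172,-1.94375,19.17804,0.13950
female,173,-1.93281,19.21113,0.13962
female,174,-1.92188,19.24434,0.13975
female,175,-1.91094,19.27766,0.13987
female,176,-1.90000,19.31111,0.14000
female,177,-1.88906,19.34468,0.14012
female,178,-1.87813,19.37836,0.14025
female,179,-1.86719,19.41217,0.14037
female,180,-1.85625,19.44609,0.14050
female,181,-1.84531,19.48014,0.14062
female,182,-1.83438,19.51430,0.14075
female,183,-1.82344,19.54858,0.14088
female,184,-1.81250,19.58299,0.14100
female,185,-1.80156,19.61751,0.14113
female,186,-1.79062,19.65215,0.14125
female,187,-1.77969,19.68691,0.14138
female,188,-1.76875,19.72179,0.14150
female,189,-1.75781,19.75679,0.14163
female,190,-1.74687,19.79191,0.14175
female,191,-1.73594,19.82714,0.14188
female,192,-1.72500,19.86250,0.14200
female,193,-1.71406,19.89798,0.14213
female,194,-1.70312,19.93357,0.14225
female,195,-1.69219,19.96929,0.14238
female,196,-1.68125,20.00512,0.14250
female,197,-1.67031,20.04108,0.14263
female,198,-1.65937,20.07715,0.14275
female,199,-1.64844,20.11334,0.14288
female,200,-1.63750,20.14965,0.14300
female,201,-1.62656,20.18608,0.14313
female,202,-1.61563,20.22263,0.14325
female,203,-1.60469,20.25930,0.14338
female,204,-1.59375,20.29609,0.14350
female,205,-1.58281,20.33300,0.14363
female,206,-1.57187,20.37003,0.14375
female,207,-1.56094,20.40718,0.14388
female,208,-1.55000,20.44444,0.14400
female,209,-1.53906,20.48183,0.14413
female,210,-1.52812,20.51934,0.14425
female,211,-1.51719,20.55696,0.14438
female,212,-1.50625,20.59470,0.14450
female,213,-1.49531,20.63257,0.14463
female,214,-1.48438,20.67055,0.14475
female,215,-1.47344,20.70865,0.14488
female,216,-1.46250,20.74688,0.14500
female,217,-1.45156,20.78522,0.14513
female,218,-1.44062,20.82368,0.14525
female,219,-1.42969,20.86226,0.14538
female,220,-1.41875,20.90095,0.14550
female,221,-1.40781,20.93977,0.14563
female,222,-1.39688,20.97871,0.14575
female,223,-1.38594,21.01777,0.14588
female,224,-1.37500,21.05694,0.14600
female,225,-1.36406,21.09624,0.14613
female,226,-1.35312,21.13566,0.14625
female,227,-1.34219,21.17519,0.14638
female,228,-1.33125,21.21484,0.14650
female,229,-1.32031,21.25462,0.14663
female,230,-1.30937,21.29451,0.14675
female,231,-1.29844,21.33452,0.14688
female,232,-1.28750,21.37465,0.14700
female,233,-1.27656,21.41490,0.14713
female,234,-1.26562,21.45527,0.14725
female,235,-1.25469,21.49576,0.14738
female,236,-1.24375,21.53637,0.14750
female,237,-1.23281,21.57710,0.14763
female,238,-1.22188,21.61795,0.14775
female,239,-1.21094,21.65891,0.14787
female,240,-1.20000,21.70000,0.14800
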