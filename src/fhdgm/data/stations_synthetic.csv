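station_id,lon,lat
ST001,8.90160,45.59354
ST002,9.48057,45.40851
ST003,8.98902,45.52884
ST004,9.06085,45.38815
ST005,9.25712,45.36738
ST006,9.07145,45.48501
ST007,9.02996,45.40519
ST008,9.26577,45.31674
ST009,9.03353,45.24674
ST010,9.19504,45.62624
ST011,9.30238,45.46661
ST012,9.57071,45.47404
ST013,9.09745,45.57993
ST014,9.13863,45.39888
ST015,9.28867,45.32497
ST016,9.38686,45.40862
ST017,9.21621,45.33907
ST018,9.08737,45.38267
ST019,9.30429,45.75162
ST020,9.77481,45.81570
ST021,9.75219,45.78477
ST022,9.62731,45.77448
ST023,9.51388,45.72454
ST024,9.83528,45.70991
ST025,9.50224,45.51788
ST026,9.59091,45.61489
ST027,10.27712,45.34522
ST028,10.34813,45.53932
ST029,10.36491,45.38527
ST030,10.08129,45.51268
ST031,10.48581,45.59162
ST032,10.49732,45.44499
ST033,10.21961,45.43183
ST034,10.44185,45.59369
ST035,9.11119,45.20924
ST036,9.03994,45.10845
ST037,9.33347,45.16911
ST038,9.03155,45.21002
ST039,9.17279,45.25213
ST040,9.17166,45.23057
ST041,9.85523,45.17424
ST042,9.96325,45.17112
ST043,10.11121,45.15354
ST044,10.06233,45.15334
ST045,9.96474,45.19914
ST046,10.76481,45.12273
ST047,10.71359,45.17626
ST048,10.79720,45.11689
ST049,10.79964,45.32056
ST050,10.69188,45.23790
ST051,9.87643,45.30321
ST052,9.84120,45.39486
ST053,9.90862,45.29177
ST054,9.79925,45.37433
ST055,8.58431,45.44950
ST056,8.61285,45.47831
ST057,8.61520,45.43171
ST058,8.60232,45.38531
ST059,8.49981,45.47327
ST060,9.49575,45.83299
ST061,9.37260,45.66522
ST062,9.37896,45.91212
ST063,9.54435,45.88208
ST064,9.39240,45.79407
ST065,8.99057,45.76426
ST066,8.95101,45.72560
ST067,9.00485,45.79877
ST068,9.16793,45.82955
ST069,9.20850,45.82288
ST070,8.77594,45.85789
ST071,8.92617,45.85913
ST072,8.80300,45.80386
ST073,8.86756,45.79668
ST074,8.87816,45.82153
ST075,9.43293,46.25652
ST076,9.69361,46.13161
ST077,9.53220,46.09793
ST078,9.65646,46.23789
ST079,9.78250,46.12398
ST080,9.38882,45.02575
ST081,9.42727,44.98085
ST082,9.51312,45.01181
ST083,9.45332,45.22335
ST084,9.29026,45.00303
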