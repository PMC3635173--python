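material,density_g_cm3,energy_kev,mu_total,mu_photoelectric,mu_incoherent
air,0.0012,10,4.79253,4.6,0.192525
air,0.0012,15,1.4716,1.28254,0.189066
air,0.0012,20,0.703986,0.518219,0.185767
air,0.0012,30,0.324093,0.144486,0.179607
air,0.0012,40,0.232349,0.0583806,0.173969
air,0.0012,50,0.197696,0.028907,0.168789
air,0.0012,60,0.180291,0.0162773,0.164013
air,0.0012,80,0.162073,0.00657695,0.155496
air,0.0012,100,0.151377,0.00325655,0.14812
air,0.0012,150,0.134256,0.000907968,0.133348
air,0.0012,200,0.122556,0.000366871,0.122189
lung,0.26,10,5.162,4.95,0.211996
lung,0.26,15,1.58831,1.38012,0.208187
lung,0.26,20,0.762202,0.557649,0.204554
lung,0.26,30,0.35325,0.15548,0.197771
lung,0.26,40,0.254385,0.0628226,0.191562
lung,0.26,50,0.216965,0.0311064,0.185859
lung,0.26,60,0.198116,0.0175158,0.1806
lung,0.26,80,0.178299,0.00707737,0.171222
lung,0.26,100,0.166604,0.00350433,0.1631
lung,0.26,150,0.147811,0.000977052,0.146833
lung,0.26,200,0.134941,0.000394785,0.134546
soft_tissue,1.04,10,5.16212,4.95,0.212124
soft_tissue,1.04,15,1.58844,1.38012,0.208312
soft_tissue,1.04,20,0.762326,0.557649,0.204677
soft_tissue,1.04,30,0.35337,0.15548,0.19789
soft_tissue,1.04,40,0.254501,0.0628226,0.191678
soft_tissue,1.04,50,0.217078,0.0311064,0.185971
soft_tissue,1.04,60,0.198225,0.0175158,0.180709
soft_tissue,1.04,80,0.178402,0.00707737,0.171325
soft_tissue,1.04,100,0.166703,0.00350433,0.163198
soft_tissue,1.04,150,0.147899,0.000977052,0.146922
soft_tissue,1.04,200,0.135022,0.000394785,0.134627
brain,1.04,10,5.11328,4.9,0.213277
brain,1.04,15,1.57563,1.36618,0.209444
brain,1.04,20,0.757806,0.552016,0.20579
brain,1.04,30,0.352875,0.153909,0.198966
brain,1.04,40,0.254908,0.0621881,0.19272
brain,1.04,50,0.217774,0.0307922,0.186982
brain,1.04,60,0.19903,0.0173388,0.181691
brain,1.04,80,0.179262,0.00700588,0.172256
brain,1.04,100,0.167554,0.00346893,0.164085
brain,1.04,150,0.148688,0.000967183,0.147721
brain,1.04,200,0.13575,0.000390797,0.135359
bone,1.4,10,20.1985,20,0.198546
bone,1.4,15,5.77123,5.57625,0.194978
bone,1.4,20,2.4447,2.25313,0.191576
bone,1.4,30,0.813423,0.6282,0.185223
bone,1.4,40,0.433238,0.253829,0.179409
bone,1.4,50,0.29975,0.125682,0.174067
bone,1.4,60,0.239913,0.0707707,0.169142
bone,1.4,80,0.188954,0.0285954,0.160359
bone,1.4,100,0.166911,0.0141589,0.152752
bone,1.4,150,0.141465,0.00394769,0.137518
bone,1.4,200,0.127605,0.00159509,0.12601
water,1.0,10,5.15411,4.94,0.214109
water,1.0,15,1.5876,1.37733,0.210262
water,1.0,20,0.763115,0.556522,0.206593
water,1.0,30,0.354908,0.155165,0.199742
water,1.0,40,0.256168,0.0626957,0.193472
water,1.0,50,0.218755,0.0310436,0.187712
water,1.0,60,0.199881,0.0174804,0.182401
water,1.0,80,0.179992,0.00706307,0.172929
water,1.0,100,0.168223,0.00349725,0.164726
water,1.0,150,0.149272,0.000975078,0.148297
water,1.0,200,0.136281,0.000393988,0.135887
pmma,1.19,10,3.20802,3,0.208025
pmma,1.19,15,1.04073,0.836438,0.204287
pmma,1.19,20,0.538691,0.337969,0.200722
pmma,1.19,30,0.288296,0.09423,0.194066
pmma,1.19,40,0.226049,0.0380743,0.187974
pmma,1.19,50,0.20123,0.0188524,0.182378
pmma,1.19,60,0.187833,0.0106156,0.177217
pmma,1.19,80,0.172304,0.00428931,0.168014
pmma,1.19,100,0.162169,0.00212384,0.160045
pmma,1.19,150,0.144675,0.000592153,0.144083
pmma,1.19,200,0.132265,0.000239264,0.132026
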