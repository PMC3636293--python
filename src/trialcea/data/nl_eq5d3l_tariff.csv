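state,utility
11111,1.0
11112,0.805
11113,0.37
11121,0.843
11122,0.719
11123,0.284
11131,0.366
11132,0.242
11133,0.041
11211,0.897
11212,0.773
11213,0.338
11221,0.811
11222,0.687
11223,0.252
11231,0.334
11232,0.21
11233,0.009
11311,0.638
11312,0.514
11313,0.313
11321,0.552
11322,0.428
11323,0.227
11331,0.309
11332,0.185
11333,-0.016
12111,0.847
12112,0.723
12113,0.288
12121,0.761
12122,0.637
12123,0.202
12131,0.284
12132,0.16
12133,-0.041
12211,0.815
12212,0.691
12213,0.256
12221,0.729
12222,0.605
12223,0.17
12231,0.252
12232,0.128
12233,-0.073
12311,0.556
12312,0.432
12313,0.231
12321,0.47
12322,0.346
12323,0.145
12331,0.227
12332,0.103
12333,-0.098
13111,0.543
13112,0.419
13113,0.218
13121,0.457
13122,0.333
13123,0.132
13131,0.214
13132,0.09
13133,-0.111
13211,0.511
13212,0.387
13213,0.186
13221,0.425
13222,0.301
13223,0.1
13231,0.182
13232,0.058
13233,-0.143
13311,0.486
13312,0.362
13313,0.161
13321,0.4
13322,0.276
13323,0.075
13331,0.157
13332,0.033
13333,-0.168
21111,0.893
21112,0.769
21113,0.334
21121,0.807
21122,0.683
21123,0.248
21131,0.33
21132,0.206
21133,0.005
21211,0.861
21212,0.737
21213,0.302
21221,0.775
21222,0.651
21223,0.216
21231,0.298
21232,0.174
21233,-0.027
21311,0.602
21312,0.478
21313,0.277
21321,0.516
21322,0.392
21323,0.191
21331,0.273
21332,0.149
21333,-0.052
22111,0.811
22112,0.687
22113,0.252
22121,0.725
22122,0.601
22123,0.166
22131,0.248
22132,0.124
22133,-0.077
22211,0.779
22212,0.655
22213,0.22
22221,0.693
22222,0.569
22223,0.134
22231,0.216
22232,0.092
22233,-0.109
22311,0.52
22312,0.396
22313,0.195
22321,0.434
22322,0.31
22323,0.109
22331,0.191
22332,0.067
22333,-0.134
23111,0.507
23112,0.383
23113,0.182
23121,0.421
23122,0.297
23123,0.096
23131,0.178
23132,0.054
23133,-0.147
23211,0.475
23212,0.351
23213,0.15
23221,0.389
23222,0.265
23223,0.064
23231,0.146
23232,0.022
23233,-0.179
23311,0.45
23312,0.326
23313,0.125
23321,0.364
23322,0.24
23323,0.039
23331,0.121
23332,-0.003
23333,-0.204
31111,0.534
31112,0.41
31113,0.209
31121,0.448
31122,0.324
31123,0.123
31131,0.205
31132,0.081
31133,-0.12
31211,0.502
31212,0.378
31213,0.177
31221,0.416
31222,0.292
31223,0.091
31231,0.173
31232,0.049
31233,-0.152
31311,0.477
31312,0.353
31313,0.152
31321,0.391
31322,0.267
31323,0.066
31331,0.148
31332,0.024
31333,-0.177
32111,0.452
32112,0.328
32113,0.127
32121,0.366
32122,0.242
32123,0.041
32131,0.123
32132,-0.001
32133,-0.202
32211,0.42
32212,0.296
32213,0.095
32221,0.334
32222,0.21
32223,0.009
32231,0.091
32232,-0.033
32233,-0.234
32311,0.395
32312,0.271
32313,0.07
32321,0.309
32322,0.185
32323,-0.016
32331,0.066
32332,-0.058
32333,-0.259
33111,0.382
33112,0.258
33113,0.057
33121,0.296
33122,0.172
33123,-0.029
33131,0.053
33132,-0.071
33133,-0.272
33211,0.35
33212,0.226
33213,0.025
33221,0.264
33222,0.14
33223,-0.061
33231,0.021
33232,-0.103
33233,-0.304
33311,0.325
33312,0.201
33313,-0.0
33321,0.239
33322,0.115
33323,-0.086
33331,-0.004
33332,-0.128
33333,-0.329
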