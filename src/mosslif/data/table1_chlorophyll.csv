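tray,sample,chl_a_per_mg,chl_b_per_mg,total_per_mg,ab_ratio_printed
1,Cont 1,4.526,1.714,6.241,1.585
2,Cont 1,3.121,1.204,4.324,1.463
3,Cont 1,2.214,0.853,3.068,0.763
1,Cont 2,4.112,1.609,5.722,1.163
2,Cont 2,4.576,1.672,6.248,1.841
3,Cont 2,2.738,0.974,3.712,1.102
1,Cont 3,4.662,1.806,6.468,2.797
2,Cont 3,2.773,1.043,3.816,0.519
3,Cont 3,5.369,2.025,7.395,2.299
1,Cont 4,3.25,1.193,4.443,1.574
2,Cont 4,7.293,2.751,10.044,3.432
3,Cont 4,5.131,1.92,7.05,1.473
1,Cont 5,3.355,1.319,4.674,1.364
2,Cont 5,2.934,1.123,4.058,1.104
3,Cont 5,3.711,1.403,5.115,1.659
1,Cont 6,2.525,1.028,3.552,1.505
2,Cont 6,3.998,1.488,5.486,1.118
3,Cont 6,9.147,3.505,12.652,2.295
1,Cont 7,4.226,1.615,5.841,2.763
2,Cont 7,3.174,1.183,4.357,0.703
3,Cont 7,2.278,0.882,3.16,1.33
1,Cont 8,5.012,1.928,6.94,1.659
2,Cont 8,4.185,1.608,5.793,0.875
3,Cont 8,3.92,1.601,5.521,1.314
1,Cont 9,4.484,1.77,6.253,1.24
2,Cont 9,3.907,1.453,5.36,1.381
3,Cont 9,2.705,0.974,3.679,1.478
1,Cont 10,4.434,1.711,6.146,2.255
2,Cont 10,7.278,2.735,10.014,5.027
3,Cont 10,1.87,0.68,2.549,0.755
1,T0-1,1.206,0.476,1.682,0.78
2,T0-1,2.273,0.926,3.199,0.638
3,T0-1,1.836,0.83,2.665,1.03
1,T0-2,2.477,0.93,3.407,0.652
2,T0-2,1.707,0.701,2.408,0.606
3,T0-2,1.615,0.65,2.265,0.574
1,T0-3,3.395,1.268,4.663,0.673
2,T0-3,3.953,1.614,5.567,0.71
3,T0-3,2.533,1.016,3.549,0.598
1,T0-4,3.682,1.641,5.324,0.896
2,T0-4,4.24,1.725,5.966,2.081
3,T0-4,2.111,0.859,2.97,0.842
1,T0-5,2.219,1.177,3.396,0.798
2,T0-5,5.225,2.129,7.354,2.191
3,T0-5,3.441,1.344,4.785,1.042
1,T0-6,1.689,0.619,2.308,0.577
2,T0-6,5.779,2.248,8.027,0.918
3,T0-6,4.022,1.509,5.531,1.026
1,T0-7,3.561,1.435,4.996,1.288
2,T0-7,2.881,1.14,4.021,0.735
3,T0-7,1.754,0.628,2.382,0.61
1,T0-8,2.339,0.943,3.282,0.889
2,T0-8,2.877,1.227,4.104,1.426
3,T0-8,2.915,1.177,4.092,0.564
1,T0-9,1.809,0.731,2.54,0.57
2,T0-9,3.632,1.554,5.186,1.359
3,T0-9,1.81,0.698,2.508,0.59
1,T0-10,3.429,1.351,4.78,2.192
2,T0-10,2.849,1.245,4.095,1.482
3,T0-10,1.999,0.745,2.744,0.533
1,T24-1,2.64,0.992,3.632,1.792
2,T24-1,3.702,1.354,5.056,1.642
3,T24-1,3.52,1.385,4.905,1.474
1,T24-2,3.615,1.332,4.947,1.144
2,T24-2,2.681,0.998,3.679,1.238
3,T24-2,5.275,1.926,7.201,1.621
1,T24-3,3.551,1.389,4.94,0.635
2,T24-3,2.152,0.784,2.936,0.995
3,T24-3,1.799,0.742,2.542,0.607
1,T24-4,2.755,1.065,3.819,0.871
2,T24-4,2.626,1.043,3.669,1.054
3,T24-4,2.161,0.792,2.952,0.964
1,T24-5,2.348,0.892,3.24,2.005
2,T24-5,2.702,0.981,3.682,1.399
3,T24-5,2.777,1.056,3.833,1.129
1,T24-6,4.465,1.756,6.221,0.636
2,T24-6,2.525,0.945,3.47,0.794
3,T24-6,1.498,0.549,2.047,1.581
1,T24-7,4.559,1.709,6.268,1.427
2,T24-7,3.311,1.188,4.499,0.971
3,T24-7,1.677,0.596,2.272,1.294
1,T24-8,6.657,2.401,9.059,2.49
2,T24-8,4.602,1.652,6.254,1.174
3,T24-8,1.712,0.668,2.38,0.954
1,T24-9,1.71,0.632,2.341,1.183
2,T24-9,4.462,1.729,6.191,0.977
3,T24-9,1.812,0.606,2.419,1.128
1,T24-10,3.957,1.48,5.437,1.186
2,T24-10,5.013,1.936,6.949,1.191
3,T24-10,1.77,0.623,2.393,1.556
1,T48-1,3.472,1.248,4.721,1.042
2,T48-1,2.278,0.842,3.12,0.79
3,T48-1,3.16,1.087,4.246,2.463
1,T48-2,3.517,1.366,4.883,1.219
2,T48-2,3.055,1.088,4.143,1.279
3,T48-2,2.013,0.68,2.693,1.346
1,T48-3,2.692,1.003,3.696,1.251
2,T48-3,4.375,1.672,6.047,0.561
3,T48-3,6.49,2.48,8.97,1.415
1,T48-4,1.996,0.752,2.748,0.987
2,T48-4,8.229,3.007,11.236,3.755
3,T48-4,3.291,1.265,4.556,1.702
1,T48-5,2.413,0.868,3.281,2.236
2,T48-5,3.986,1.475,5.461,1.201
3,T48-5,2.946,1.123,4.07,1.347
1,T48-6,2.091,0.762,2.853,0.985
2,T48-6,3.117,1.206,4.323,1.434
3,T48-6,2.559,0.867,3.426,2.726
1,T48-7,2.889,1.005,3.894,1.326
2,T48-7,3.473,1.269,4.742,1.526
3,T48-7,6.746,2.636,9.383,1.876
1,T48-8,3.817,1.434,5.251,1.499
2,T48-8,4.453,1.666,6.119,0.964
3,T48-8,3.498,1.307,4.806,0.801
1,T48-9,2.055,0.783,2.839,1.133
2,T48-9,3.218,1.168,4.386,2.727
3,T48-9,2.642,1.082,3.724,2.134
1,T48-10,0.733,0.262,0.995,0.681
2,T48-10,5.311,1.919,7.231,1.523
3,T48-10,1.785,0.644,2.429,1.651
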