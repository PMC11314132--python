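tray,sample,cu_ww,cu_dw
1,Control 1,0.135,0.657
2,Control 1,0.073,0.27
3,Control 1,0.027,0.169
1,Control 2,0.047,0.232
2,Control 2,0.028,0.147
3,Control 2,0.043,0.261
1,Control 3,0.049,0.215
2,Control 3,0.023,0.129
3,Control 3,0.04,0.107
1,Control 4,0.058,0.258
2,Control 4,0.037,0.218
3,Control 4,0.042,0.29
1,Control 5,0.05,0.358
2,Control 5,0.034,0.233
3,Control 5,0.03,0.201
1,Time 0-1,0.09,0.304
2,Time 0-1,0.21,1.524
3,Time 0-1,2.124,14.47
1,Time 0-2,0.113,0.409
2,Time 0-2,0.261,2.136
3,Time 0-2,2.258,11.109
1,Time 0-3,0.126,0.524
2,Time 0-3,0.099,0.965
3,Time 0-3,1.351,11.039
1,Time 0-4,0.079,0.352
2,Time 0-4,0.176,1.061
3,Time 0-4,2.106,13.178
1,Time 0-5,0.098,0.387
2,Time 0-5,0.286,2.42
3,Time 0-5,1.593,12.76
1,Time 0-6,0.084,0.39
2,Time 0-6,0.069,0.434
3,Time 0-6,1.613,10.272
1,Time 0-7,0.06,0.346
2,Time 0-7,0.18,1.648
3,Time 0-7,2.065,15.628
1,Time 0-8,0.185,0.48
2,Time 0-8,0.133,1.094
3,Time 0-8,0.989,8.377
1,Time 0-9,0.059,0.334
2,Time 0-9,0.121,1.195
3,Time 0-9,2.396,18.085
1,Time 0-10,0.108,0.275
2,Time 0-10,0.195,1.578
3,Time 0-10,2.426,21.176
1,Time 24-1,0.135,0.531
2,Time 24-1,0.173,0.79
3,Time 24-1,2.047,12.101
1,Time 24-2,0.083,0.387
2,Time 24-2,0.184,0.891
3,Time 24-2,0.894,6.601
1,Time 24-3,0.068,0.331
2,Time 24-3,0.122,0.965
3,Time 24-3,3.789,18.376
1,Time 24-4,0.059,0.337
2,Time 24-4,0.207,1.541
3,Time 24-4,1.48,10.655
1,Time 24-5,0.095,0.355
2,Time 24-5,0.158,1.458
3,Time 24-5,1.495,7.566
1,Time 24-6,0.032,0.251
2,Time 24-6,0.426,1.659
3,Time 24-6,2.727,19.67
1,Time 24-7,0.063,0.279
2,Time 24-7,0.199,1.103
3,Time 24-7,2.184,12.659
1,Time 24-8,0.067,0.356
2,Time 24-8,0.236,1.4
3,Time 24-8,0.696,5.298
1,Time 24-9,0.05,0.367
2,Time 24-9,0.17,1.37
3,Time 24-9,2.138,13.261
1,Time 24-10,0.088,0.399
2,Time 24-10,0.101,0.753
3,Time 24-10,1.254,8.152
1,Time 48-1,0.091,0.457
2,Time 48-1,0.181,1.022
3,Time 48-1,2.285,13.269
1,Time 48-2,0.101,0.358
2,Time 48-2,0.233,1.148
3,Time 48-2,0.983,6.9
1,Time 48-3,0.058,0.361
2,Time 48-3,0.188,1.114
3,Time 48-3,2.035,11.327
1,Time 48-4,0.056,0.276
2,Time 48-4,0.44,2.323
3,Time 48-4,1.148,6.357
1,Time 48-5,0.089,0.289
2,Time 48-5,0.214,1.199
3,Time 48-5,1.719,10.314
1,Time 48-6,0.127,0.408
2,Time 48-6,0.208,1.254
3,Time 48-6,1.722,5.176
1,Time 48-7,0.064,0.297
2,Time 48-7,0.257,0.76
3,Time 48-7,2.124,10.785
1,Time 48-8,0.063,0.333
2,Time 48-8,0.242,1.107
3,Time 48-8,1.814,14.474
1,Time 48-9,0.098,0.361
2,Time 48-9,0.249,1.47
3,Time 48-9,0.755,5.778
1,Time 48-10,0.124,0.457
2,Time 48-10,0.339,1.497
3,Time 48-10,1.886,13.694
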