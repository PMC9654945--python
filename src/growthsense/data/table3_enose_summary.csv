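channel,time_h,mean,sd,n,letters
S1,0,0.754,0.020,20,g
S1,12,0.772,0.014,20,f
S1,24,0.769,0.013,20,f
S1,36,0.783,0.017,20,e
S1,48,0.787,0.008,20,e
S1,60,0.789,0.014,20,e
S1,72,0.804,0.012,20,d
S1,84,0.826,0.010,20,b
S1,96,0.806,0.013,20,cd
S1,108,0.810,0.012,20,cd
S1,120,0.819,0.022,20,bc
S1,132,0.822,0.011,20,b
S1,144,0.851,0.013,20,a
S1,156,0.847,0.033,20,a
S1,168,0.842,0.029,20,a
S2,0,16.176,2.912,20,a
S2,12,13.414,1.918,20,b
S2,24,12.626,2.205,20,b
S2,36,10.269,3.127,20,d
S2,48,11.444,1.352,20,c
S2,60,9.672,1.278,20,de
S2,72,8.997,1.217,20,ef
S2,84,8.170,0.705,20,fg
S2,96,8.627,1.105,20,f
S2,108,8.220,1.179,20,fg
S2,120,7.406,1.410,20,g
S2,132,6.375,0.805,20,h
S2,144,5.727,0.651,20,h
S2,156,4.738,1.115,20,i
S2,168,4.737,0.989,20,i
S3,0,0.881,0.011,20,h
S3,12,0.891,0.007,20,g
S3,24,0.888,0.008,20,g
S3,36,0.898,0.007,20,f
S3,48,0.896,0.004,20,f
S3,60,0.899,0.007,20,f
S3,72,0.907,0.007,20,e
S3,84,0.919,0.005,20,b
S3,96,0.908,0.007,20,de
S3,108,0.910,0.006,20,de
S3,120,0.915,0.013,20,cd
S3,132,0.916,0.006,20,bc
S3,144,0.931,0.006,20,a
S3,156,0.933,0.015,20,a
S3,168,0.931,0.015,20,a
S4,0,1.065,0.007,20,a
S4,12,1.051,0.006,20,b
S4,24,1.047,0.004,20,c
S4,36,1.051,0.009,20,b
S4,48,1.048,0.008,20,bc
S4,60,1.047,0.005,20,c
S4,72,1.045,0.005,20,c
S4,84,1.041,0.013,20,d
S4,96,1.040,0.003,20,de
S4,108,1.037,0.002,20,ef
S4,120,1.037,0.003,20,ef
S4,132,1.034,0.003,20,fg
S4,144,1.034,0.003,20,fg
S4,156,1.035,0.005,20,fg
S4,168,1.033,0.004,20,g
S5,0,0.915,0.005,20,j
S5,12,0.924,0.005,20,hi
S5,24,0.922,0.005,20,i
S5,36,0.929,0.005,20,g
S5,48,0.926,0.003,20,h
S5,60,0.930,0.005,20,g
S5,72,0.934,0.004,20,f
S5,84,0.943,0.003,20,c
S5,96,0.936,0.004,20,ef
S5,108,0.938,0.004,20,de
S5,120,0.941,0.008,20,d
S5,132,0.943,0.004,20,c
S5,144,0.954,0.004,20,b
S5,156,0.958,0.008,20,a
S5,168,0.956,0.009,20,ab
S6,0,1.776,0.093,20,a
S6,12,1.670,0.071,20,b
S6,24,1.633,0.035,20,bc
S6,36,1.651,0.065,20,bc
S6,48,1.623,0.033,20,c
S6,60,1.639,0.064,20,bc
S6,72,1.566,0.034,20,de
S6,84,1.492,0.040,20,g
S6,96,1.575,0.040,20,d
S6,108,1.567,0.033,20,de
S6,120,1.536,0.055,20,def
S6,132,1.535,0.030,20,ef
S6,144,1.455,0.043,20,h
S6,156,1.522,0.083,20,f
S6,168,1.527,0.093,20,f
S7,0,10.719,0.942,20,a
S7,12,9.445,0.995,20,b
S7,24,9.115,0.865,20,bc
S7,36,8.733,1.298,20,c
S7,48,7.937,1.016,20,d
S7,60,7.676,0.992,20,def
S7,72,7.731,0.610,20,de
S7,84,7.243,0.656,20,fg
S7,96,7.318,0.550,20,efg
S7,108,7.171,0.586,20,gh
S7,120,6.778,0.382,20,hi
S7,132,6.673,0.496,20,ij
S7,144,6.245,0.578,20,jk
S7,156,5.947,0.756,20,kl
S7,168,5.724,0.604,20,l
S8,0,1.358,0.039,20,ab
S8,12,1.337,0.035,20,ab
S8,24,1.335,0.019,20,ab
S8,36,1.345,0.034,20,a
S8,48,1.317,0.020,20,c
S8,60,1.328,0.033,20,bc
S8,72,1.293,0.019,20,d
S8,84,1.244,0.021,20,f
S8,96,1.293,0.023,20,d
S8,108,1.284,0.018,20,de
S8,120,1.270,0.028,20,e
S8,132,1.271,0.015,20,e
S8,144,1.221,0.022,20,g
S8,156,1.241,0.042,20,f
S8,168,1.254,0.046,20,f
S9,0,6.022,0.433,20,a
S9,12,5.334,0.491,20,b
S9,24,5.124,0.375,20,b
S9,36,4.816,0.561,20,c
S9,48,4.557,0.401,20,d
S9,60,4.451,0.395,20,d
S9,72,4.356,0.282,20,d
S9,84,4.073,0.283,20,e
S9,96,4.129,0.258,20,e
S9,108,4.019,0.248,20,ef
S9,120,3.851,0.193,20,fg
S9,132,3.802,0.224,20,g
S9,144,3.590,0.272,20,h
S9,156,3.387,0.310,20,i
S9,168,3.215,0.287,20,i
S10,0,1.113,0.005,20,cd
S10,12,1.116,0.005,20,bc
S10,24,1.113,0.004,20,cd
S10,36,1.130,0.008,20,a
S10,48,1.127,0.012,20,a
S10,60,1.127,0.009,20,a
S10,72,1.127,0.008,20,a
S10,84,1.108,0.004,20,ef
S10,96,1.125,0.007,20,a
S10,108,1.119,0.007,20,b
S10,120,1.115,0.008,20,bc
S10,132,1.111,0.007,20,de
S10,144,1.105,0.006,20,fg
S10,156,1.101,0.008,20,g
S10,168,1.106,0.006,20,f
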