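time_h,pc1,pc2,pc3,pc4,score
0,5.50,3.34,-0.51,-1.84,3.83
12,3.73,1.64,-1.07,0.00,2.50
24,3.38,0.50,-0.65,0.64,2.14
36,3.16,0.17,-0.37,1.67,2.02
48,1.94,0.50,0.80,0.85,1.37
60,2.13,-0.50,0.39,0.18,1.25
72,1.33,-1.87,1.32,0.34,0.58
84,-0.53,-2.28,-0.66,-0.44,-0.81
96,0.90,-1.68,0.94,-0.45,0.28
108,-2.08,-0.03,1.16,0.09,-1.19
120,-3.31,1.41,2.39,-0.37,-1.61
132,-2.42,-0.53,-0.83,-1.34,-1.70
144,-3.59,-2.38,-1.32,-1.35,-2.79
156,-5.24,0.81,-1.80,1.72,-3.08
168,-4.89,0.90,0.20,0.29,-2.79
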