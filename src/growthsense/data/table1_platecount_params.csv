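model,lag_h,mu_max_per_h,r2,rmse,n0_log_cfu,nmax_log_cfu
modified_gompertz,45.000,0.013,0.953,0.132,3.878,6.117
logistic,108.400,0.062,0.971,0.103,3.992,5.341
huang,55.180,0.015,0.944,0.143,3.975,6.558
baranyi,97.850,0.064,0.971,0.104,3.996,5.337
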