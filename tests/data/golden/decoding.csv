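subject,signal,balanced_accuracy,n_reps,n_folds,chance,seed
S00,osc_alpha,0.8666666666666667,3,5,0.5,693650678
S00,ap_alpha,1.0,3,5,0.5,693650678
S00,mix_alpha,0.9666666666666667,3,5,0.5,693650678
S00,slope,0.7333333333333333,3,5,0.5,693650678
S00,intercept,0.6,3,5,0.5,693650678
S01,osc_alpha,1.0,3,5,0.5,447839439
S01,ap_alpha,0.9,3,5,0.5,447839439
S01,mix_alpha,1.0,3,5,0.5,447839439
S01,slope,0.43333333333333335,3,5,0.5,447839439
S01,intercept,0.6,3,5,0.5,447839439
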