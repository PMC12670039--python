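family,signal,test,statistic,df,p,p_adjusted,method
decoding_vs_chance,osc_alpha,one_sample_t(one),6.500000000000002,1.0,0.04858979034752893,0.06073723793441116,BH
decoding_vs_chance,ap_alpha,one_sample_t(one),9.000000000000002,1.0,0.035223287477277265,0.058705479128795444,BH
decoding_vs_chance,mix_alpha,one_sample_t(one),29.00000000000001,1.0,0.010971855616010977,0.027429639040027445,BH
decoding_vs_chance,slope,one_sample_t(one),0.5555555555555551,1.0,0.3385855327829049,0.3385855327829049,BH
decoding_vs_chance,intercept,one_sample_t(one),inf,1.0,0.0,0.0,BH
mi_vs_zero,osc_alpha,one_sample_t(two),19.050794124567,1.0,0.03338632675699331,0.05775174598556771,BH
mi_vs_zero,ap_alpha,one_sample_t(two),17.154684265132435,1.0,0.03706860077707767,0.05775174598556771,BH
mi_vs_zero,mix_alpha,one_sample_t(two),75.08960141017444,1.0,0.00847763377059004,0.0423881688529502,BH
mi_vs_zero,slope,one_sample_t(two),0.8255028786205321,1.0,0.5606692094316037,0.5606692094316037,BH
mi_vs_zero,intercept,one_sample_t(two),13.755032664848967,1.0,0.04620139678845417,0.05775174598556771,BH
decoding_signal_anova,osc_alpha+ap_alpha+mix_alpha,rm_anova_oneway,0.18918918918918973,2.0,0.8409090909090905,0.8409090909090905,none
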