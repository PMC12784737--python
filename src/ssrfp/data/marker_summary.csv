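marker,size_min_bp,size_max_bp,n_alleles,mean_alleles_total,mean_alleles_cip,mean_alleles_study,nei_uncorrected,nei_corrected,nei_pct_change,pic_simple,pic_em,pic_pct_change
IBS11,236,260,8,3.42,3.21,3.58,0.817,0.820,0.46,0.79,0.81,2.28
IBS141,123,149,11,4.38,4.36,4.41,0.870,0.873,0.35,0.86,0.84,1.83
IBS199,171,212,12,4.09,4.32,3.92,0.857,0.860,0.38,0.84,0.82,2.79
IbJ116A,205,250,10,3.45,3.21,3.62,0.801,0.804,0.44,0.77,0.71,8.18
IbE2,109,142,11,3.22,2.89,3.46,0.836,0.840,0.43,0.82,0.81,1.22
IBS30,189,241,9,3.48,3.39,3.54,0.787,0.791,0.46,0.76,0.72,4.96
IBS82,141,163,8,3.68,4.09,3.43,0.814,0.818,0.45,0.79,0.78,1.13
IBS28,187,228,11,4.42,4.21,4.58,0.852,0.855,0.36,0.84,0.82,2.19
IBC12,111,132,8,3.65,3.68,3.62,0.813,0.817,0.42,0.79,0.76,3.71
IBS139,304,348,12,3.46,3.29,3.59,0.838,0.842,0.44,0.82,0.82,0.60
IBY44,183,216,8,4.06,4.07,4.05,0.829,0.832,0.37,0.81,0.79,1.58
IBS44,127,151,8,3.46,3.39,3.51,0.844,0.848,0.45,0.83,0.83,0.02
IbJ10a,191,220,7,3.41,3.30,3.50,0.841,0.845,0.46,0.82,0.84,1.74
IbJ522a,226,265,5,2.26,2.25,2.27,0.664,0.668,0.53,0.62,0.56,9.11
IBS14,192,200,3,2.08,2.11,2.05,0.642,0.645,0.52,0.57,0.64,13.37
IbJ1809,143,155,5,3.36,3.57,3.19,0.778,0.782,0.47,0.74,0.73,1.42
IBY60,188,206,8,3.76,4.15,3.47,0.812,0.816,0.43,0.79,0.77,2.04
IBS24,149,169,6,3.53,3.56,3.51,0.781,0.785,0.44,0.75,0.72,4.25
IbJ544b,191,211,6,2.17,2.04,2.27,0.625,0.629,0.58,0.56,0.55,3.28
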