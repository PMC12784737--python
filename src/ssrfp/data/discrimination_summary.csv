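marker,n_alleles,n_patterns,confusion,discriminating_power,dl_limit
IBS11,8,21,0.07,0.93,0.91
IBS141,11,21,0.06,0.94,0.92
IBS199,12,21,0.06,0.94,0.92
IbJ116A,10,21,0.08,0.92,0.91
IbE2,11,20,0.07,0.93,0.92
IBS30,9,16,0.10,0.90,0.89
IBS82,8,19,0.11,0.89,0.88
IBS28,11,22,0.06,0.94,0.93
IBC12,8,18,0.10,0.90,0.89
IBS139,13,22,0.06,0.94,0.92
IBY44,8,16,0.09,0.91,0.90
IBS44,8,21,0.06,0.94,0.92
IbJ10a,7,19,0.07,0.93,0.91
IbJ522a,5,8,0.15,0.85,0.84
IBS14,3,6,0.21,0.79,0.78
IbJ1809,5,13,0.13,0.87,0.86
IbY60,8,20,0.10,0.90,0.89
IBS24,6,11,0.14,0.86,0.85
IbJ544b,6,8,0.27,0.73,0.72
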