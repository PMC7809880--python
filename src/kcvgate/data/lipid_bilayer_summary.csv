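channel,bilayer,n,g_ps,g_sd_ps,po,po_sd,po_voltage_mv
Kcv_S,PC,10,92,9,0.40,0.10,-100
Kcv_S,PS,9,120,6,0.89,0.06,-100
Kcv_NTS,PC,6,82,12,0.93,0.01,-100
Kcv_NTS,PS,7,107,5,0.97,0.01,-100
Kcv_PBCV1,PC,8,139,11,0.01,0.004,100
Kcv_PBCV1,PS,6,191,11,0.12,0.10,100
Kcv_NH,PC,3,98,2,0.47,0.02,60
Kcv_NH,PS,3,138,4,0.72,0.06,60
Kcv_MT325,PC,15,34,6,0.59,0.14,160
Kcv_MT325,PG,10,47,6,0.70,0.08,160
Kcv_GLD,PC,7,38,4,0.72,0.07,160
Kcv_GLD,PG,9,91,16,0.44,0.05,160
Kmpv_12T,PC,10,37,5,0.21,0.08,-100
Kmpv_12T,PS,4,62,4,0.10,0.05,-100
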