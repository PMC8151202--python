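drug,dose_mg,metric,predicted,observed
metformin,750,cmax_ug_per_ml,1.22,1.5
metformin,500,cmax_ug_per_ml,0.95,1.55
cimetidine,400,cmax_ug_per_ml,2.06,2.20
cimetidine,300,cmax_ug_per_ml,1.53,1.53
pyrimethamine,50,cmax_ug_per_ml,0.57,0.76
pyrimethamine,50,cmax_ug_per_ml,0.57,0.37
pyrimethamine,75,cmax_ug_per_ml,0.86,0.86
pyrimethamine,75,cmax_ug_per_ml,0.86,0.60
trimethoprim,210,cmax_ug_per_ml,2.18,2.35
trimethoprim,1400,cmax_ug_per_ml,13.76,12.78
ondansetron,8,cmax_ug_per_ml,0.046,0.0272
ondansetron,8,cmax_ug_per_ml,0.046,0.037
rabeprazole,40,cmax_ug_per_ml,0.40,0.502
rabeprazole,40,cmax_ug_per_ml,0.40,0.444
rabeprazole,20,cmax_ug_per_ml,0.20,0.252
verapamil,40,cmax_ug_per_ml,0.050,0.033
verapamil,80,cmax_ug_per_ml,0.099,0.13
metformin,750,auc_ug_h_per_ml,11.05,9.4
metformin,500,auc_ug_h_per_ml,7.04,9.08
cimetidine,400,auc_ug_h_per_ml,9.17,8.03
cimetidine,300,auc_ug_h_per_ml,6.68,5.22
pyrimethamine,50,auc_ug_h_per_ml,31.18,76
pyrimethamine,50,auc_ug_h_per_ml,31.18,42.83
pyrimethamine,75,auc_ug_h_per_ml,46.77,124.6
pyrimethamine,75,auc_ug_h_per_ml,46.77,68.34
trimethoprim,210,auc_ug_h_per_ml,28.26,37.1
trimethoprim,1400,auc_ug_h_per_ml,302.34,299.31
ondansetron,8,auc_ug_h_per_ml,0.203,0.198
ondansetron,8,auc_ug_h_per_ml,0.233,0.254
rabeprazole,40,auc_ug_h_per_ml,1.27,1.315
rabeprazole,40,auc_ug_h_per_ml,1.27,1.332
rabeprazole,20,auc_ug_h_per_ml,0.63,0.575
verapamil,40,auc_ug_h_per_ml,0.28,0.22
verapamil,80,auc_ug_h_per_ml,0.564,0.387
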