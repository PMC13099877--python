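region,model,mae,rmse,aic,bic,minmax_score,zscore_score
PC,GLM-Poisson_rf,1.785,2.558,12398.460,12736.250,0.029,-1.676
PC,GLM-NegBin_rf,1.780,2.608,11732.010,12075.840,0.222,-1.145
PC,DLNM-ZIP,1.469,2.210,10992.310,11529.160,0.898,0.444
PC,DLNM-ZINBI,1.476,2.237,10825.780,11368.670,0.931,0.542
PC,DLNM-Poisson_rf,1.450,2.182,10915.300,11452.150,0.954,0.580
PC,DLNM-NegBin_rf,1.455,2.202,10771.750,11314.630,0.985,0.670
PC,DLNM-ZIP_rf,1.450,2.183,10898.830,11453.730,0.955,0.585
PN,GLM-Poisson_rf,3.499,5.129,23541.300,23901.530,0.028,-1.693
PN,GLM-NegBin_rf,3.513,5.157,22520.000,22886.540,0.416,-0.605
PN,DLNM-ZIP,3.267,4.721,22843.380,23405.830,0.706,0.030
PN,DLNM-ZINBI,3.286,4.774,22204.150,22772.920,0.919,0.640
PN,DLNM-Poisson_rf,3.247,4.693,22821.550,23384.000,0.749,0.136
PN,DLNM-NegBin_rf,3.270,4.748,22204.880,22773.660,0.948,0.709
PN,DLNM-ZIP_rf,3.247,4.692,22802.780,23390.420,0.751,0.144
PN,DLNM-ZINBI_rf,3.287,4.774,22204.160,22772.990,0.918,0.638
PS,GLM-Poisson_rf,3.187,4.673,27386.570,27753.030,0.070,-1.666
PS,GLM-NegBin_rf,3.210,4.726,26487.680,26860.680,0.277,-0.852
PS,DLNM-ZIP,3.047,4.528,26583.890,27166.290,0.556,-0.206
PS,DLNM-ZINBI,3.050,4.500,26399.690,26988.630,0.633,0.050
PS,DLNM-Poisson_rf,2.974,4.436,26245.750,26828.150,0.818,0.571
PS,DLNM-NegBin_rf,2.981,4.459,25654.000,26242.950,0.973,1.154
PS,DLNM-ZIP_rf,2.974,4.437,26218.870,26833.930,0.820,0.579
PS,DLNM-ZINBI_rf,3.015,4.462,26253.590,26874.640,0.743,0.371
RA,GLM-Poisson_rf,4.292,5.770,33765.130,34131.530,0.135,-1.705
RA,GLM-NegBin_rf,4.467,6.106,30928.610,31301.550,0.302,-1.129
RA,DLNM-ZIP,3.770,5.173,30577.350,31159.660,0.770,0.095
RA,DLNM-ZINBI,3.808,5.228,29244.000,29832.860,0.887,0.466
RA,DLNM-Poisson_rf,3.663,5.070,30130.690,30713.000,0.876,0.391
RA,DLNM-NegBin_rf,3.678,5.096,28976.190,29565.050,0.988,0.740
RA,DLNM-ZIP_rf,3.664,5.071,30083.320,30698.320,0.879,0.400
RA,DLNM-ZINBI_rf,3.678,5.096,28950.060,29571.590,0.989,0.743
RMS,GLM-Poisson_rf,1.800,2.292,9157.490,9478.260,0.166,-1.067
RMS,GLM-NegBin_rf,1.801,2.294,9095.490,9421.890,0.354,-0.480
RMS,DLNM-ZIP,1.737,2.227,9073.770,9574.620,0.527,-0.263
RMS,DLNM-ZINBI,1.736,2.228,9041.210,9547.690,0.626,0.043
RMS,DLNM-Poisson_rf,1.721,2.204,9042.990,9543.840,0.743,0.318
RMS,DLNM-NegBin_rf,1.722,2.206,9015.580,9522.060,0.816,0.549
RMS,DLNM-ZIP_rf,1.722,2.205,9033.980,9545.990,0.749,0.339
RMS,DLNM-ZINBI_rf,1.722,2.206,9008.770,9526.370,0.820,0.562
RN,GLM-Poisson_rf,2.598,3.389,26935.300,27301.700,0.023,-1.673
RN,GLM-NegBin_rf,2.606,3.394,26231.330,26604.280,0.361,-0.669
RN,DLNM-ZIP,2.511,3.266,26466.560,27048.570,0.550,-0.320
RN,DLNM-ZINBI,2.515,3.272,26000.700,26589.550,0.771,0.338
RN,DLNM-Poisson_rf,2.476,3.224,26282.280,26864.590,0.774,0.262
RN,DLNM-NegBin_rf,2.478,3.227,25846.510,26435.370,0.988,0.895
RN,DLNM-ZIP_rf,2.477,3.224,26254.970,26869.820,0.777,0.272
RN,DLNM-ZINBI_rf,2.478,3.227,25830.140,26451.240,0.987,0.894
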