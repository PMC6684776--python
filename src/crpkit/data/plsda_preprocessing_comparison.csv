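preprocessing,latent_variables,rmsec,rmsecv,rmsep,published_deviation_pct,r2_cal,r2_cv,r2_val
none,3,0.2260,0.2481,0.1944,-16.2551,0.7966,0.7572,0.7474
snv+mean_center,2,0.0687,0.0749,0.0671,-2.3845,0.9808,0.9772,0.9837
normalize_sum+mean_center,2,0.1034,0.1114,0.0938,-10.2345,0.9565,0.9495,0.9654
mean_center+normalize_sum,2,0.1538,0.1738,0.1469,-4.6971,0.9046,0.8778,0.9206
mean_center+snv,2,0.1324,0.1507,0.1518,12.7799,0.9288,0.9076,0.9139
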