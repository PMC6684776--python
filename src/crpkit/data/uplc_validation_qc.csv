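compound,spiked_ug_ml,period,n,observed_mean,observed_sd,published_rsd_pct,published_accuracy_pct
calycosin-7-O-b-D-glucoside,250,intraday,6,252.995,0.914,0.361,1.197
calycosin-7-O-b-D-glucoside,500,intraday,6,519.093,2.716,0.523,3.818
calycosin-7-O-b-D-glucoside,1000,intraday,6,967.190,2.325,0.240,-3.281
formononetin,50,intraday,6,50.963,0.876,1.719,1.927
formononetin,100,intraday,6,98.997,1.349,1.362,-1.002
formononetin,200,intraday,6,189.891,1.312,0.691,-5.084
calycosin,160,intraday,6,161.065,0.898,0.558,0.666
calycosin,320,intraday,6,316.580,0.800,0.253,-1.069
calycosin,640,intraday,6,637.987,2.264,0.355,-0.315
medicarpin,200,intraday,6,209.377,0.941,0.449,4.688
medicarpin,400,intraday,6,372.762,0.470,0.126,-6.810
medicarpin,800,intraday,6,789.892,1.051,0.133,-1.271
ononin,375,intraday,6,382.684,0.762,0.199,2.049
ononin,750,intraday,6,763.594,0.921,0.121,1.812
ononin,1500,intraday,6,1507.782,1.069,0.071,0.518
calycosin-7-O-b-D-glucoside,250,interday,18,257.999,3.793,1.470,3.199
calycosin-7-O-b-D-glucoside,500,interday,18,520.266,2.424,0.466,4.053
calycosin-7-O-b-D-glucoside,1000,interday,18,975.803,7.011,0.718,-2.451
formononetin,50,interday,18,50.081,1.116,2.227,0.162
formononetin,100,interday,18,101.801,2.857,2.806,1.801
formononetin,200,interday,18,193.855,4.552,2.348,-3.072
calycosin,160,interday,18,160.424,0.999,0.623,0.265
calycosin,320,interday,18,317.512,1.646,0.518,-0.777
calycosin,640,interday,18,636.471,3.514,0.552,-0.551
medicarpin,200,interday,18,204.941,4.969,2.425,2.470
medicarpin,400,interday,18,376.282,3.831,1.018,-5.929
medicarpin,800,interday,18,790.642,3.315,0.419,-1.169
ononin,375,interday,18,384.5343,2.083,0.542,2.542
ononin,750,interday,18,758.200,4.755,0.627,1.093
ononin,1500,interday,18,1496.51,9.334,0.623,-0.233
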