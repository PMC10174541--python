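disinfectant,concentration,time_min,contamination_mean,contamination_se,germination_mean,germination_se
MWCNT,0,5,96.8,0.18,16.6,0.26
MWCNT,0,10,96.8,0.18,16.6,0.26
MWCNT,0,15,96.8,0.18,16.6,0.26
MWCNT,50,5,48.95,1.18,48.95,0.54
MWCNT,50,10,43.75,0.92,29.16,0.70
MWCNT,50,15,56.25,1.67,30.2,0.82
MWCNT,100,5,60.41,0.75,40.62,0.44
MWCNT,100,10,55.2,1.03,42.7,0.87
MWCNT,100,15,43.75,0.88,38.54,0.75
MWCNT,150,5,45.83,0.75,43.75,0.79
MWCNT,150,10,69.79,0.98,29.16,0.70
MWCNT,150,15,60.41,0.55,33.33,0.65
MWCNT,200,5,79.16,0.77,22.91,0.45
MWCNT,200,10,93.75,0.52,10.41,0.49
MWCNT,200,15,66.66,0.96,32.29,0.83
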