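disinfectant,concentration,time_min,contamination_mean,contamination_se,germination_mean,germination_se
NaOCl,0,5,96.8,0.18,16.6,0.26
NaOCl,0,10,96.8,0.18,16.6,0.26
NaOCl,0,15,96.8,0.18,16.6,0.26
NaOCl,0.5,5,54.1,0.858,42.7,1.09
NaOCl,0.5,10,42.7,0.69,62.5,0.5
NaOCl,0.5,15,44.7,0.26,62.5,0.7
NaOCl,1,5,73.9,0.58,39.5,0.25
NaOCl,1,10,55.2,0.32,54.1,0.82
NaOCl,1,15,29.1,0.42,71.8,0.0375
NaOCl,1.5,5,29.1,1.37,69.7,1.11
NaOCl,1.5,10,14.5,0.94,62.5,0.65
NaOCl,1.5,15,16.6,0.59,75,0.86
NaOCl,2,5,16.6,0.60,79,0.62
NaOCl,2,10,15.6,0.61,72.9,0.9
NaOCl,2,15,7.0,0.62,80.2,0.49
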