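disinfectant,concentration,time_min,contamination_mean,contamination_se,germination_mean,germination_se
H2O2,0,10,96.8,0.18,16.6,0.26
H2O2,0,15,96.8,0.18,16.6,0.26
H2O2,0,20,96.8,0.18,16.6,0.26
H2O2,10,10,31.25,0.59,66.66,0.56
H2O2,10,15,28.12,0.62,63.54,0.53
H2O2,10,20,27.08,0.61,61.45,0.41
H2O2,12.5,10,14.58,0.67,66.66,0.46
H2O2,12.5,15,15.62,0.63,62.5,0.73
H2O2,12.5,20,27.08,1.16,55.2,1.08
H2O2,15,10,6.25,0.49,78.12,0.41
H2O2,15,15,7.29,0.22,67.7,0.61
H2O2,15,20,16.66,0.73,67.7,0.58
H2O2,17.5,10,4.16,0.26,55.2,0.44
H2O2,17.5,15,1.04,0.12,62.5,0.42
H2O2,17.5,20,4.16,0.26,59.37,0.39
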