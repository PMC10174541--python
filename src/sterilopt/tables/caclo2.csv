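disinfectant,concentration,time_min,contamination_mean,contamination_se,germination_mean,germination_se
CaClO2,0,5,96.8,0.18,16.6,0.26
CaClO2,0,10,96.8,0.18,16.6,0.26
CaClO2,0,15,96.8,0.18,16.6,0.26
CaClO2,6,5,5.20,0.49,87.5,0.53
CaClO2,6,10,3.12,0.37,82.29,0.95
CaClO2,6,15,6.25,0.52,58.33,0.32
CaClO2,7,5,0,0.0,76.04,0.35
CaClO2,7,10,4.16,0.5,64.58,0.75
CaClO2,7,15,8.33,0.65,61.45,0.37
CaClO2,8,5,3.12,0.37,79.16,0.56
CaClO2,8,10,4.16,0.5,65.62,1.11
CaClO2,8,15,4.16,0.5,80.2,0.59
CaClO2,9,5,11.45,0.62,72.91,0.49
CaClO2,9,10,4.16,0.5,91.66,0.37
CaClO2,9,15,6.25,0.75,80.20,0.84
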