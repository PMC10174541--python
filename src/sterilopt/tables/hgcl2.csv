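disinfectant,concentration,time_min,contamination_mean,contamination_se,germination_mean,germination_se
HgCl2,0,3,96.8,0.18,16.6,0.26
HgCl2,0,6,96.8,0.18,16.6,0.26
HgCl2,0,12,96.8,0.18,16.6,0.26
HgCl2,1,3,5.2,0.69,67.7,0.49
HgCl2,1,6,9.37,0.54,59.37,0.65
HgCl2,1,12,14.58,0.58,73.99,0.49
HgCl2,2,3,14.58,0.74,57.29,0.59
HgCl2,2,6,14.58,0.75,61.45,0.375
HgCl2,2,12,12.51,0.46,61.45,0.12
HgCl2,4,3,12.51,0.67,63.54,0.0
HgCl2,4,6,13.53,0.41,69.79,0.25
HgCl2,4,12,16.66,0.86,64.58,0
HgCl2,6,3,12.5,0.51,73.95,0.26
HgCl2,6,6,7.29,0.77,61.45,0.26
HgCl2,6,12,10.41,0.67,36.45,0.0
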