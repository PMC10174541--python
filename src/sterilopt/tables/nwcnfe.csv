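disinfectant,concentration,time_min,contamination_mean,contamination_se,germination_mean,germination_se
NWCNFe,0,10,96.8,0.18,16.6,0.26
NWCNFe,0,15,96.8,0.18,16.6,0.26
NWCNFe,0,20,96.8,0.18,16.6,0.26
NWCNFe,2.5,10,80.20,0.49,30.20,0.80
NWCNFe,2.5,15,75,0.70,33.33,0.96
NWCNFe,2.5,20,53.12,1.30,47.91,1.29
NWCNFe,5,10,34.37,1.00,60.41,0.70
NWCNFe,5,15,43.75,0.81,58.33,0.90
NWCNFe,5,20,38.54,0.90,50,0.75
NWCNFe,7.5,10,31.25,0.45,55.20,0.53
NWCNFe,7.5,15,66.66,0.84,32.29,1.39
NWCNFe,7.5,20,55.20,1.22,30.20,1.23
NWCNFe,10,10,62.5,1.25,30.20,1.01
NWCNFe,10,15,37.5,0.90,62.5,1.11
NWCNFe,10,20,61.45,0.56,41.66,1.03
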