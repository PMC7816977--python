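run,ratio_parts,polymer,dc,de15,de60,mdt,f2
SD1,1,PVP K25,95.52,35.23,75.66,11.56,15.88
SD2,1,PVP K25,93.98,33.31,73.12,12.55,17.61
SD3,2,PVP K25,93.99,52.71,71.66,13.78,14.52
SD4,2,PVP K25,89.76,51.28,72.55,12.86,15.67
SD5,4,PVP K25,96.00,28.57,76.97,10.88,20.20
SD6,1,PVP K90,92.61,31.79,63.13,19.10,21.98
SD7,1,PVP K90,89.45,29.65,61.18,20.88,23.07
SD8,2,PVP K90,93.59,13.69,40.03,28.47,42.10
SD9,2,PVP K90,96.20,15.05,42.70,26.81,39.36
SD10,4,PVP K90,96.52,36.98,67.33,15.99,17.10
SD11,1,PEG 4000,93.13,39.29,54.82,14.11,25.14
SD12,2,PEG 4000,96.71,27.50,43.93,16.52,35.77
SD13,2,PEG 4000,100.68,27.37,41.95,18.16,36.74
SD14,4,PEG 4000,98.89,39.97,70.55,16.04,18.18
SD15,1,PEG 8000,98.76,68.13,81.65,8.12,10.64
SD16,2,PEG 8000,92.47,46.57,77.08,10.88,14.81
SD17,2,PEG 8000,91.30,44.81,75.17,11.60,15.70
SD18,4,PEG 8000,98.01,78.35,95.92,4.55,6.36
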