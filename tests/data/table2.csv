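land_use,pGreen,no2_seq1,no2_seq2,food1,food2,CN1,CN2
Edible private garden,0.6,0.07,0.09,0.2,6.6,85,88
Community garden,1.0,0.07,0.09,0.2,2.2,85,88
Commercial garden,1.0,0.07,0.09,4.0,6.6,85,85
Rooftop garden,1.0,0.07,0.07,0.2,2.2,67,88
Hydroponic rooftop,1.0,0.07,0.07,9.0,19.0,98,98
Arable land,0.6,0.00,0.07,4.0,6.6,85,88
Normal garden,0.6,0.07,0.07,1.0,1.0,74,86
Permanent crops,0.6,0.09,0.09,4.0,6.6,65,77
Vacant,1.0,0.07,0.09,1.0,1.0,74,87
Grass,1.0,0.07,0.07,1.0,1.0,74,86
Mulcher,1.0,0.00,0.00,1.0,1.0,88,88
Raised bed,1.0,0.07,0.07,1.0,1.0,67,88
Trees,1.0,0.11,0.11,1.0,1.0,70,77
Vegetated pergola,1.0,0.07,0.07,1.0,1.0,98,98
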