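sex,age_years,L,M,S,cutoff_thin2,cutoff_thin1,cutoff_overweight,cutoff_obese
female,14.0,-1.4,19.2,0.115,14.834,15.771,23.53,28.68
female,14.5,-1.39,19.375,0.1145,14.979,15.924,23.715,28.846
female,15.0,-1.38,19.55,0.114,15.124,16.077,23.9,29.012
female,15.5,-1.37,19.725,0.1135,15.269,16.23,24.084,29.177
female,16.0,-1.36,19.9,0.113,15.415,16.384,24.268,29.342
female,16.5,-1.35,20.075,0.1125,15.561,16.537,24.451,29.507
female,17.0,-1.34,20.25,0.112,15.707,16.691,24.635,29.672
female,17.5,-1.33,20.425,0.1115,15.853,16.846,24.817,29.836
female,18.0,-1.32,20.6,0.111,16.0,17.0,25.0,30.0
male,14.0,-1.8,18.9,0.12,14.556,15.466,23.064,28.224
male,14.5,-1.785,19.125,0.1195,14.736,15.657,23.307,28.447
male,15.0,-1.77,19.35,0.119,14.916,15.848,23.55,28.67
male,15.5,-1.755,19.575,0.1185,15.096,16.04,23.793,28.892
male,16.0,-1.74,19.8,0.118,15.276,16.231,24.035,29.114
male,16.5,-1.725,20.025,0.1175,15.457,16.423,24.277,29.336
male,17.0,-1.71,20.25,0.117,15.638,16.615,24.518,29.558
male,17.5,-1.695,20.475,0.1165,15.819,16.807,24.759,29.779
male,18.0,-1.68,20.7,0.116,16.0,17.0,25.0,30.0
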