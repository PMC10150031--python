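sample_id,area
Y-1,6611
Y-2,8952
Y-3,9747.5
Y-4,8243
Y-5,5956
G-1,7650
G-2,9692.5
G-3,7359.5
G-4,9813
G-5,11227
P-1,3917.5
P-2,7227.5
P-3,4999
P-4,4861
P-5,6277.5
Z-1,7305
Z-2,5289.5
Z-3,8593.5
Z-4,5464.5
Z-5,6706.5
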