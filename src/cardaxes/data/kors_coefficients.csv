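component,I,II,V1,V2,V3,V4,V5,V6
X,0.38,-0.07,-0.13,0.05,-0.01,0.14,0.06,0.54
Y,-0.07,0.93,0.06,-0.02,-0.05,0.06,-0.17,0.13
Z,0.11,-0.23,-0.43,-0.06,-0.14,-0.20,-0.11,0.31
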