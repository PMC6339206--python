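,D1,D2,D3,D4
D1,0.0,3.5,2.2,2.0
D2,2.9,0.0,3.3,2.1
D3,1.7,3.0,0.0,1.9
D4,2.6,2.8,1.7,0.0
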