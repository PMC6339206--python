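,C21,C22,C23,C24,C25,C26
C21,0.0,3.1,2.4,2.8,3.5,3.0
C22,3.2,0.0,2.2,2.1,3.3,3.1
C23,2.3,2.3,0.0,1.5,2.2,2.6
C24,2.8,2.6,1.5,0.0,3.0,2.4
C25,3.5,3.5,2.2,2.9,0.0,3.1
C26,3.4,3.0,2.3,2.8,3.1,0.0
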