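,C31,C32,C33,C34
C31,0.0,1.7,3.3,2.9
C32,1.9,0.0,1.3,1.4
C33,3.3,1.3,0.0,3.4
C34,3.4,1.5,3.2,0.0
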