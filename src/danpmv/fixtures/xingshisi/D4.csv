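,C41,C42,C43,C44,C45,C46,C47,C48,C49
C41,0.0,2.7,3.0,1.6,2.8,2.6,2.5,1.7,1.5
C42,2.9,0.0,1.7,2.3,2.9,3.0,2.6,2.7,2.4
C43,2.8,2.5,0.0,2.4,2.9,3.0,2.1,2.4,2.4
C44,2.0,1.9,2.2,0.0,2.5,2.1,1.9,1.9,1.5
C45,1.7,2.3,2.2,1.8,0.0,2.1,1.5,1.8,1.7
C46,2.8,3.0,2.2,1.9,2.2,0.0,1.7,1.5,1.5
C47,2.8,2.2,1.8,1.7,1.9,1.9,0.0,2.3,1.9
C48,2.6,2.5,2.2,2.1,2.3,1.8,2.2,0.0,2.2
C49,2.0,2.0,2.0,1.7,2.1,1.5,1.7,1.5,0.0
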