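,C11,C12,C13,C14,C15,C16,C17
C11,0.0,3.5,3.5,3.1,3.0,3.0,3.2
C12,3.0,0.0,2.8,2.2,2.3,2.3,2.3
C13,2.6,2.0,0.0,2.8,2.7,3.1,2.9
C14,2.2,1.9,2.8,0.0,1.9,3.1,3.1
C15,2.7,2.5,3.1,2.4,0.0,2.6,2.6
C16,1.9,1.5,2.6,2.3,2.3,0.0,2.0
C17,1.7,1.6,2.3,1.6,1.9,2.1,0.0
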