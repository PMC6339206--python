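alternative,criterion,score
xingshisi,C11,5.104
xingshisi,C12,4.083
xingshisi,C13,5.542
xingshisi,C14,4.958
xingshisi,C15,5.688
xingshisi,C16,6.125
xingshisi,C17,2.333
xingshisi,C21,7.000
xingshisi,C22,5.906
xingshisi,C23,3.938
xingshisi,C24,4.375
xingshisi,C25,6.781
xingshisi,C26,6.708
xingshisi,C31,7.000
xingshisi,C32,0.875
xingshisi,C33,6.344
xingshisi,C34,6.781
xingshisi,C41,7.000
xingshisi,C42,7.000
xingshisi,C43,6.563
xingshisi,C44,7.000
xingshisi,C45,6.781
xingshisi,C46,7.000
xingshisi,C47,7.000
xingshisi,C48,6.563
xingshisi,C49,7.000
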