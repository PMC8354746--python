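id,converts
0,False
1,False
2,True
3,False
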