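id,x,y,phase,mean_speed
0,0.0,0.0,LIVE_CORAL,0.0
1,0.04330127018922194,0.024999999999999998,FLUID,0.02
2,-0.060621778264910706,0.03499999999999999,FLUID,0.045
3,-1.469576158976824e-17,-0.08000000000000002,FLUID,0.07
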