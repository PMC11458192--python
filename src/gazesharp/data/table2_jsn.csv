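,0,1,2,3,4,5,≥6
0,261,2,1,1,0,0,0
1,4,19,1,0,0,0,0
2,0,14,14,0,1,0,0
3,1,3,20,20,0,0,1
4,0,0,5,11,16,0,1
5,0,0,0,0,0,0,0
≥6,0,0,0,0,0,0,0
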