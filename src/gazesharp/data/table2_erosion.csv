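,0,1,2,3,4,5,≥6
0,307,1,0,0,0,0,0
1,3,35,3,0,0,0,0
2,0,13,33,1,0,0,0
3,0,0,0,6,1,0,0
4,0,0,0,0,1,4,0
5,0,0,0,0,0,1,3
≥6,0,0,0,0,0,1,1
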