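Rule1,Rule2,Rule3,Rule4,Rule5,Rule6,Rule7,Rule8,Rule9,Rule10,Rule11,Rule12,Rule13,Rule14,Rule15
0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
0,0,0,0,1,1,1,0,0,0,0,0,0,1,1
0,0,0,0,0,0,1,0,0,0,0,0,0,0,1
0,0,0,0,0,0,0,1,0,0,1,0,0,1,1
0,0,0,0,1,0,0,0,0,0,0,1,1,0,0
1,0,0,0,1,0,0,0,0,0,0,0,0,0,1
1,0,0,1,0,0,0,0,0,0,0,0,0,0,1
1,1,1,0,1,0,1,0,0,0,0,0,0,0,0
0,0,0,0,1,0,0,0,0,0,0,0,0,0,0
1,0,0,0,0,0,0,0,0,0,0,0,0,0,0
0,0,0,0,1,0,1,0,0,1,1,0,0,1,0
0,0,0,0,1,1,1,0,1,1,1,0,1,1,0
0,0,0,0,1,0,0,0,0,1,0,0,0,0,1
1,0,0,0,1,0,0,0,0,0,0,0,0,0,1
0,0,0,0,0,0,1,0,0,0,0,0,0,0,0
0,0,0,1,1,0,0,0,0,0,0,0,0,0,0
0,0,0,0,0,0,0,0,0,0,1,1,1,0,1
0,0,0,1,0,0,0,0,0,0,1,0,0,1,1
1,0,0,1,0,0,0,0,0,0,0,0,0,1,0
0,0,0,0,0,0,0,0,1,1,0,0,0,0,0
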