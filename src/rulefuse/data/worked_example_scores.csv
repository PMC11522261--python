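Y,probability
-0.3265,0.419092
1.2106,0.770405
0.5059,0.623845
0.7161,0.671748
0.5388,0.631533
-0.9616,0.276558
-0.9826,0.272376
-1.8375,0.137347
-0.5802,0.358887
-1.097,0.250302
1.5013,0.817768
2.8422,0.944914
0.4067,0.600296
-0.9616,0.276558
0.1168,0.529167
-0.8549,0.298406
1.6431,0.837956
0.8283,0.695995
-0.7928,0.311568
0.7993,0.689825
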