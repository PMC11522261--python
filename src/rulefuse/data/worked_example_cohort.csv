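original_shape_MajorAxisLength,original_firstorder_10Percentile,original_firstorder_90Percentile,original_glcm_JointEntropy,wavelet-LLH_firstorder_Maximum,wavelet-LLH_glszm_LargeAreaHighGrayLevelEmphasis,lbp-3D-k_glcm_Imc2,lbp-3D-m1_glrlm_LongRunEmphasis,spiculated margin,pleural indentation,outcome
8.9573,-871.2802,-199.0796,9.8886,350.1253,387303.7738,0.1255,26.7636,0.0,0.0,0
13.2408,-552.3181,-24.4785,9.3755,518.8299,8969.3604,0.012,44.8131,1.0,1.0,0
13.896,-845.9699,-169.4724,9.3984,460.6943,36014.2744,0.1604,42.2205,0.0,1.0,0
10.6089,-694.9142,-786.135,8.9144,330.3386,17404.0929,0.1279,35.1057,0.0,1.0,0
10.869,-443.563,-352.4161,7.321,126.0633,1166.0811,0.058,26.171,1.0,0.0,1
8.6711,-1006.1428,-297.4856,9.208,15.5956,31358.9493,0.3399,47.7371,1.0,1.0,0
7.7979,-868.8351,-362.1999,8.8945,199.4866,13593.9236,0.0738,22.8194,0.0,1.0,0
7.8248,-786.8447,-104.3518,7.2153,405.4807,4323.3883,0.0305,25.5042,1.0,0.0,0
7.6352,-686.0138,-576.5284,8.4089,575.8063,151578.8253,0.2993,12.1756,1.0,0.0,0
12.3627,-905.7852,-402.0185,8.2722,362.8054,9537.6585,0.2143,29.9012,0.0,0.0,0
9.6631,-728.2335,-178.7522,9.4367,538.3554,35106.7092,0.1485,22.5455,1.0,0.0,1
10.1194,-703.4113,-111.5422,8.874,615.728,14544.6065,0.0716,25.9985,1.0,0.0,1
8.3511,-679.5373,-251.2457,8.9789,810.7948,8464.5266,0.2016,9.3703,1.0,1.0,0
7.4665,-986.6048,-100.6026,8.9456,475.9307,16350.7265,0.0707,15.2383,1.0,1.0,0
7.2565,-622.4277,-191.5682,8.0032,669.1068,51800.9019,0.1664,24.2688,0.0,0.0,0
7.9406,-508.3758,-460.0756,7.6217,467.4996,8738.9177,0.072,15.041,1.0,1.0,0
11.3836,-647.6081,-60.1017,8.8343,231.8168,2756.496,0.1059,34.6525,0.0,1.0,1
9.8453,-786.774,-365.9635,8.624,66.6971,172669.4116,0.0607,65.953,0.0,1.0,1
8.7424,-773.612,-557.1973,8.7914,477.5582,33884.898,0.1949,25.4985,0.0,0.0,0
9.231,-1017.557,-205.5339,8.7002,572.1553,6327.3848,0.0328,31.4705,0.0,0.0,0
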