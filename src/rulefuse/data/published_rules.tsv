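id	source	rule
Rule1	AdaBoost	original_shape_MajorAxisLength <  = 12.46 & original_firstorder_10Percentile <  =  −768.75 & wavelet-LLH_glszm_LargeAreaHighGrayLevelEmphasis <  = 45,043.45 & wavelet-LLH_firstorder_Maximum <  = 487.20
Rule2	AdaBoost	original_glcm_JointEntropy <  = 8.48 & original_shape_MajorAxisLength <  = 10.01 & original_firstorder_10Percentile <  =  −658.70 & wavelet-LLH_firstorder_Maximum ∈ (122.71,525.63]
Rule3	AdaBoost	original_shape_MajorAxisLength <  = 9.93 & original_firstorder_10Percentile <  =  −607.30 & original_glcm_JointEntropy <  = 8.70 & wavelet-LLH_firstorder_Maximum ∈ (122.71,523.14]
Rule4	Gradient boosting	lbp-3D-k_glcm_Imc2 <  = 0.20 & original_shape_MajorAxisLength <  = 9.93 & original_firstorder_90Percentile <  =  −336.0
Rule5	Gradient boosting/Random forest	spiculated margin
Rule6	AdaBoost	original_glcm_JointEntropy > 8.48 & original_firstorder_10Percentile >  −848.55 & lbp-3D-k_glcm_Imc2 <  = 0.10 & wavelet-LLH_firstorder_Maximum > 403.11
Rule7	AdaBoost	original_firstorder_90Percentile >  −200.55 & lbp-3D-m1_glrlm_LongRunEmphasis > 18.23 & original_firstorder_10Percentile <  =  −499.90 & original_glcm_JointEntropy <  = 9.74 & wavelet-LLH_firstorder_Maximum > 331.59
Rule8	Gradient boosting	gbc_wavelet-LLH_firstorder_Maximum <  = 511.67 & wavelet-LLH_glszm_LargeAreaHighGrayLevelEmphasis <  = 176,581.82 & lbp-3D-k_glcm_Imc2 > 0.04 & original_firstorder_90Percentile <  =  −405.40 & original_shape_MajorAxisLength > 9.93
Rule9	Gradient boosting	gbc_lbp-3D-m1_glrlm_LongRunEmphasis <  = 48.18 & original_shape_MajorAxisLength > 8.84 & original_firstorder_90Percentile >  −336.0 & original_glcm_JointEntropy <  = 9.29 & wavelet-LLH_firstorder_Maximum > 478.69
Rule10	Gradient boosting	gbc_original_shape_MajorAxisLength > 8.33 & lbp-3D-m1_glrlm_LongRunEmphasis <  = 32.81 & wavelet-LLH_firstorder_Maximum > 511.67
Rule11	AdaBoost	original_shape_MajorAxisLength > 8.96 & original_glcm_JointEntropy > 8.48 & original_firstorder_10Percentile >  −839.90 & original_firstorder_90Percentile <  =  −39.80
Rule12	AdaBoost	original_shape_MajorAxisLength > 9.93 & lbp-3D-m1_glrlm_LongRunEmphasis ∈ (22.03, 35.69] & wavelet-LLH_glszm_LargeAreaHighGrayLevelEmphasis <  = 8320.79 & original_firstorder_90Percentile >  −458.35
Rule13	AdaBoost	original_shape_MajorAxisLength > 9.85 & lbp-3D-m1_glrlm_LongRunEmphasis ∈ (22.03,35.69] & original_firstorder_90Percentile >  −419.95 & original_firstorder_10Percentile >  −849.00
Rule14	AdaBoost	wavelet-LLH_glszm_LargeAreaHighGrayLevelEmphasis > 5460.49 & original_glcm_JointEntropy > 8.48 & wavelet-LLH_firstorder_Maximum <  = 669.96 & original_firstorder_10Percentile >  −839.90
Rule15	Random forest	rf_original_glcm_JointEntropy > 8.48 & pleural indentation = 1
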