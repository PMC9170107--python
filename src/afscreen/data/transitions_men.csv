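age_band,p_s0e1,p_s0e2,p_t1e1,p_t1e2,p_t0e1,p_t0e2,p_e1e2
65-69,0.429%,1.318%,1.006%,1.916%,1.381%,2.254%,2.471%
70-74,0.429%,1.977%,1.006%,2.874%,1.381%,3.381%,3.707%
75-79,0.715%,3.259%,2.074%,4.738%,2.849%,5.574%,6.112%
80-84,0.715%,5.865%,2.074%,8.525%,2.849%,10.029%,10.997%
85-89,1.062%,10.654%,2.655%,15.485%,3.646%,18.218%,19.976%
90-94,1.062%,18.384%,2.655%,26.721%,3.646%,31.436%,34.469%
95-99,1.062%,29.693%,2.655%,43.159%,3.646%,50.775%,55.675%
100+,0.000%,100.000%,0.000%,100.000%,0.000%,100.000%,100.000%
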