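age_band,p_s0e1,p_s0e2,p_t1e1,p_t1e2,p_t0e1,p_t0e2,p_e1e2
65-69,0.244%,0.543%,1.016%,0.790%,1.395%,0.929%,1.019%
70-74,0.244%,0.818%,1.016%,1.189%,1.395%,1.399%,1.534%
75-79,0.551%,1.471%,2.095%,2.138%,2.877%,2.515%,2.758%
80-84,0.551%,3.008%,2.095%,4.372%,2.877%,5.144%,5.640%
85-89,1.073%,6.158%,2.682%,8.951%,3.683%,10.530%,11.547%
90-94,1.073%,12.302%,2.682%,17.880%,3.683%,21.036%,23.066%
95-99,1.073%,23.173%,2.682%,33.682%,3.683%,39.626%,43.450%
100+,0.000%,100.000%,0.000%,100.000%,0.000%,100.000%,100.000%
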