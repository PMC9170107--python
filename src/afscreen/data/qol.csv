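parameter,value
u_baseline,1.0
acute_decrement,0.14
acute_duration_years,0.25
u_poststroke_65_74,0.68
u_poststroke_75plus,0.56
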