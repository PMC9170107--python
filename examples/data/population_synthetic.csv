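sex,age_band,count
men,65-69,4000000
men,70-74,4300000
men,75-79,3200000
men,80-84,2200000
women,65-69,4200000
women,70-74,4600000
women,75-79,3900000
women,80-84,3100000
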