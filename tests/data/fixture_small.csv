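cohort_id,start_year,year_index,prevalence
c1,2001,1,0.0202
c1,2001,2,0.0259
c1,2001,3,0.02826
c1,2001,4,0.028860000000000004
c1,2001,5,0.028240000000000005
c1,2001,6,0.027259999999999996
c2,2002,1,0.0202
c2,2002,2,0.0259
c2,2002,3,0.02826
c2,2002,4,0.028860000000000004
c2,2002,5,0.028240000000000005
c2,2002,6,0.027259999999999996
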