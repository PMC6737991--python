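# Fertilizer products available to farmers in the Odisha deployment.
# Grades are N-P2O5-K2O mass percentages; prices are farmgate, averaged
# across districts and seasons, in US$ per kg (1 US$ = 65 INR).
name,grade_n,grade_p2o5,grade_k2o,price_usd_per_kg
urea,46,0,0,0.09
MOP,0,0,60,0.26
DAP,18,46,0,0.38
SSP,0,16,0,0.14
zinc sulfate,0,0,0,1.08
28-28-0,28,28,0,0.38
20-20-0,20,20,0,0.44
10-26-26,10,26,26,0.36
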