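system,pf_pd_ratio,source
lipid bilayer,1.0,Finkelstein 1987
gramicidin A,5.3,Finkelstein 1987
aquaporin AQP1,12.7,Mathai et al. 1996
collodion (densest),36,Robbins & Mauro 1960
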