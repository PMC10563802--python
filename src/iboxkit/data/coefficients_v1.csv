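variant,factor,level,hazard_ratio,log_hazard_ratio
full,time_years,,1.08,0.0769610411361
full,egfr,,0.96,-0.0408219945203
full,log_upcr,,1.5,0.405465108108
full,dsa_mfi,<1400,1,0
full,dsa_mfi,>=1400,1.84,0.609765571621
full,ifta,0-1,1,0
full,ifta,2,1.14,0.131028262406
full,ifta,3,1.41,0.34358970439
full,gptc,0-2,1,0
full,gptc,3-4,1.43,0.357674444272
full,gptc,5-6,1.84,0.609765571621
full,it,0-2,1,0
full,it,>=3,1.33,0.285178942234
full,cg,0,1,0
full,cg,>=1,1.47,0.385262400791
abbreviated,time_years,,1.12,0.113328685307
abbreviated,egfr,,0.95,-0.0512932943876
abbreviated,log_upcr,,1.59,0.463734016232
abbreviated,dsa_mfi,<1400,1,0
abbreviated,dsa_mfi,>=1400,1.84,0.609765571621
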