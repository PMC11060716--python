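# Bohaiornithid specimen mass estimates (g), transcribed from the published
# summary table of regression-based masses (13 specimens, 7 taxa).
specimen,taxon,ontogenetic_stage,mean_mass_g,min_mass_g,max_mass_g
CUGB P1202,Bohaiornithidae indet.,1,113,91,135
MHGU-F307/8,Beiguornis khinganensis,2a,260,210,310
IVPP V17963,Bohaiornis guoi,3c,300,242,358
LPM B00167,Bohaiornis guoi,2b,249,201,298
IVPP V17964,Longusunguis kurochkini,2b,171,137,204
IVPP V18693,Longusunguis kurochkini,3a,237,191,283
IVPP V18691,Parabohaiornis martini,2b,221,178,263
IVPP V28398,Parabohaiornis martini,3b,323,260,386
DNHM D2950/1,Shenqiornis mengi,2a,340,274,406
BMNHC-Ph805,Sulcavis geeorum,3b,333,268,397
BMNHC-Ph1204,cf. Sulcavis,2a,171,137,204
BMNHC-Ph756,Zhouornis hani,2a,253,204,303
CNUVB-903,Zhouornis hani,3c,758,611,905
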