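# Published per-mouse MLH1 focus-count summaries for male Peromyscus
# (wild P. leucopus, laboratory-raised P. leucopus, laboratory-raised
# P. maniculatus bairdii). One row per mouse: number of scored
# spermatocytes, mean foci per cell, sample SD, SE, CV (percent).
species,status,mouse_id,n_cells,mean,sd,se,cv
P. leucopus,wild,MAD_m1,26,23.269,0.667,0.131,2.865
P. leucopus,wild,MAD_m3,28,23.393,0.832,0.157,3.555
P. leucopus,wild,MAD_m6,12,22.917,1.084,0.313,4.728
P. leucopus,wild,MAD_m7,19,23.474,1.219,0.28,5.192
P. leucopus,wild,MAD_m18,37,23,1.179,0.194,5.124
P. leucopus,wild,MAD_m11,30,24.533,1.279,0.234,5.215
P. leucopus,wild,MAD_m12,28,23.607,0.956,0.181,4.05
P. leucopus,wild,MAD_m23,15,23.533,1.302,0.336,5.533
P. leucopus,wild,MAD_m24,26,23.808,1.877,0.368,7.882
P. leucopus,lab,LL_m1,33,22.909,1.487,0.259,6.489
P. leucopus,lab,LL_m3,29,22.552,1.594,0.296,7.07
P. leucopus,lab,LL_m4,23,22.217,1.93,0.402,8.685
P. leucopus,lab,LL_m5,22,23,1.69,0.36,7.349
P. leucopus,lab,LL_m6,22,23.318,0.839,0.179,3.597
P. leucopus,lab,LL_m7,29,21.862,1.382,0.257,6.32
P. leucopus,lab,LL_m8,28,22.107,1.685,0.318,7.623
P. leucopus,lab,LL_m9,28,23.107,1.397,0.264,6.045
P. leucopus,lab,LL_m10,29,22.552,1.682,0.312,7.456
P. m. bairdii,lab,BW_m1,22,23,1.543,0.329,6.709
P. m. bairdii,lab,BW_m2,31,22.774,1.146,0.206,5.033
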