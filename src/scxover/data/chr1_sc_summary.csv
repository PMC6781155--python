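# Published per-mouse chromosome-1 synaptonemal-complex summaries for male
# Peromyscus. One row per mouse: number of scored chromosome-1 bivalents,
# mean SC length (micrometres), sample SD, SE, counts of bivalents carrying
# 0/1/2/3 MLH1 foci, and the mean intra-chromosomal r-bar.
species,status,mouse_id,n_bivalents,mean_um,sd,se,n0,n1,n2,n3,rbar
P. leucopus,wild,MAD_m1,21,13.264,1.218,0.266,0,13,8,0,0.239
P. leucopus,wild,MAD_m3,21,14.137,1.608,0.351,0,15,6,0,0.228
P. leucopus,wild,MAD_m7,8,13.174,1.017,0.36,0,2,6,0,0.248
P. leucopus,wild,MAD_m9,8,12.939,0.929,0.328,1,2,5,0,0.243
P. leucopus,wild,MAD_m11,19,12.194,0.919,0.211,0,4,15,0,0.268
P. leucopus,wild,MAD_m12,9,12.486,0.554,0.185,0,5,4,0,0.259
P. leucopus,wild,MAD_m18,14,12.291,1.379,0.369,0,11,3,0,0.232
P. leucopus,wild,MAD_m23,10,13.520,1.093,0.346,0,7,2,1,0.249
P. leucopus,wild,MAD_m24,11,13.921,1.142,0.344,0,3,8,0,0.272
P. leucopus,lab,LL_m1,10,12.022,1.329,0.42,1,5,3,1,0.221
P. leucopus,lab,LL_m2,5,12.256,1.03,0.461,0,4,1,0,0.233
P. leucopus,lab,LL_m3,12,12.300,0.735,0.212,0,6,5,1,0.256
P. leucopus,lab,LL_m4,11,12.682,0.896,0.27,0,5,6,0,0.244
P. leucopus,lab,LL_m5,9,13.060,0.650,0.194,0,6,3,0,0.241
P. leucopus,lab,LL_m6,10,12.628,0.756,0.239,0,7,3,0,0.242
P. leucopus,lab,LL_m7,13,12.583,0.83,0.23,0,9,4,0,0.214
P. leucopus,lab,LL_m8,14,13.009,1.162,0.311,0,9,4,1,0.220
P. leucopus,lab,LL_m9,9,11.819,0.966,0.322,1,6,2,0,0.223
P. leucopus,lab,LL_m10,11,12.546,0.861,0.26,0,10,1,0,0.207
P. m. bairdii,lab,BW_m1,12,13.446,1.571,0.454,0,12,0,0,0.205
P. m. bairdii,lab,BW_m2,10,12.308,0.652,0.206,0,9,1,0,0.210
P. m. bairdii,lab,BW_m3,8,11.375,0.428,0.139,0,7,1,0,0.233
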