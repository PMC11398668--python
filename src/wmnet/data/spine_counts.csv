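area,spine_count,n_positive,n_negative,lobe
V1,643,2,3,Occipital
V2,1201,1,0,Occipital
V4,2429,2,3,Occipital
TEO,4812,0,0,Occipital
MT,2077,0,5,Temporal
TEpd,7260,2,2,Temporal
STPc,8337,1,0,Temporal
STPi,8337,1,0,Temporal
STPr,8337,1,0,Temporal
7A,2572,7,1,Parietal
7M,2294,0,0,Parietal
LIP,2316,7,0,Parietal
7B,6841,0,0,Parietal
3,3060,0,3,Parietal
8M,3200,18,0,Prefrontal
5,4689,1,0,Prefrontal
8L,3200,15,0,Prefrontal
46d,6600,24,0,Prefrontal
10,6488,0,1,Prefrontal
9/46d,7800,30,2,Prefrontal
9/46v,7800,30,2,Prefrontal
9,6225,1,0,Prefrontal
12,7622,8,0,Prefrontal
13,7205,4,1,Prefrontal
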