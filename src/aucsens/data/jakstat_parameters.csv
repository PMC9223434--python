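index,name,description,ranked
1,kv,cytoplasmic/nuclear volume ratio,True
2,vi1t,IRF1 transcription rate,True
3,vs1t,STAT1 transcription rate,True
4,vl2t,LMP2 transcription rate,True
5,vt1t,TAP1 transcription rate,True
6,ktransl,translation rate,True
7,T,time constant for inertial elements,True
8,ks1deg,STAT1 degradation rate,True
9,ks1pdeg,STAT1p degradation rate,True
10,ks2deg,STAT2 degradation rate,True
11,ks2pdeg,STAT2p degradation rate,True
12,ki1deg,IRF1active degradation rate,True
13,ki1_indeg,IRF1inactive degradation rate,True
14,ks1t_deg,STAT1 transcript degradation rate,True
15,ks2t_deg,STAT2 transcript degradation rate,True
16,ki1t_deg,IRF1 transcript degradation rate,True
17,kl2t_deg,LMP2 transcript degradation rate,True
18,kt1t_deg,TAP1 transcript degradation rate,True
19,kinv_s1s1,cyt. [STAT1p|STAT1p] dissociation rate,True
20,kinv_s1s1_n,nuc. [STAT1p|STAT1p] dissociation rate,True
21,kinv_s1s2,cyt. [STAT1p|STAT2p] dissociation rate,True
22,kinv_s1s2_n,nuc. [STAT1p|STAT2p] dissociation rate,True
23,kinv_phys1s1,nuc. [STAT1p|STAT1p|PHY] dissociation rate,True
24,kinv_s1i1,nuc. [STAT1|IRF1active] dissociation rate,True
25,ks1i1deg,[STAT1|IRF1] degradation rate,True
26,ks1s1,[STAT1p|STAT1p] complex creation rate,True
27,ks1s2,[STAT1p|STAT2p] complex creation rate,True
28,kphys1s1,[PHY|STAT1p|STAT1p] complex creation rate,True
29,ks1i1,nuc. [IRF1|STAT1] complex creation rate,True
30,kactivation,PHY activation,True
31,kinacti1,IRF1 inactivation rate,True
32,ks1tprod,STAT1 constitutive mRNA production rate,True
33,ks2tprod,STAT2 constitutive mRNA production rate,True
34,kl2tprod,LMP2 constitutive mRNA production rate,True
35,kt1tprod,TAP1 constitutive mRNA production rate,True
36,es1,STAT1 nuclear export,True
37,is1,STAT1 nuclear import,True
38,es2,STAT2 nuclear export,True
39,is2,STAT2 nuclear import,True
40,is1s1,[STAT1p|STAT1p] nuclear import,True
41,is1s2,[STAT1p|STAT2p] nuclear import,True
42,ii1,IRF1active nuclear import,True
43,ei1,IRF1active nuclear export,True
44,ei1_in,IRF1inactive nuclear export,True
45,ks1_phos,STAT1 phosphorylation rate,True
46,ks1_dephc,STAT1p dephosphorylation rate,True
47,ks2_phos,STAT2 phosphorylation rate,True
48,ks2_dephc,STAT2p dephosphorylation rate,True
49,ks1_phos_sat,STAT1 phosphorylation saturation constant (held at nominal value),False
50,ks2_phos_sat,STAT2 phosphorylation saturation constant (held at nominal value),False
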