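index,name,description,ranked
1,a6,Max DNA damage rate,True
2,q3,Coefficient governing apoptotic factor synthesis,True
3,d9,Apoptotic factors degradation rate,True
4,p1,Max synthesis rate of apoptotic factor,True
5,a0,Spontaneous p53n phosphorylation rate,True
6,a1,DSB-induced p53n phosphorylation rate,True
7,a2,PIP activation rate,True
8,a3,AKT activation rate,True
9,a4,Mdm2 phosphorylation rate,True
10,c0,PIPp dephosphorylation rate (by PTEN),True
11,c1,AKTp inactivation rate,True
12,c2,Mdm2p dephosphorylation rate,True
13,c3,Spontaneous p53pn dephosphorylation rate,True
14,p0,p53n production rate,True
15,s0,Mdm2 transcription rate,True
16,s1,PTEN transcription rate,True
17,t0,Mdm2 translation rate,True
18,t1,PTEN translation rate,True
19,d0,Mdm2 spontaneous deg. rate (all Mdm2 forms),True
20,d1,DSB-induced Mdm2 deg. rate (all Mdm2 forms),True
21,d2,PTEN degradation rate,True
22,d3,Spontaneous p53n degradation rate,True
23,d4,Mdm2pn-induced p53n degradation rate,True
24,d5,Spontaneous p53pn degradation rate,True
25,d6,Mdm2pn-induced p53pn degradation rate,True
26,d7,Mdm2t degradation rate,True
27,d8,PTENt degradation rate,True
28,i0,Mdm2p nuclear import,True
29,e0,Mdm2pn nuclear export,True
30,AKTtot,Total number of Akt molecules (AKT+AKTp),True
31,PIPtot,Total number of PIP molecules (PIP+PIPp),True
32,drep,DNA repair rate,True
33,q0,Spontaneous activation of Mdm2 and PTEN genes,True
34,q1,p53pn-depended activation of Mdm2 and PTEN genes,True
35,q2,Mdm2 and PTEN genes inactivation rate,True
36,h0,Michaelis-Menten coefficient (held at nominal value),False
37,NSAT,Saturation constant (held at nominal value),False
38,dDAM,Saturation constant (held at nominal value),False
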