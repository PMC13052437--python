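index,metal_salt,mole_ratio,solvent,temperature,duration,heating_mode,yield_percent
1,PdCl2,2,PhCN,191,15 m,MW,0
2,PdCl2,2,PhCN,191,45 m,MW,0
3,PdCl2,2,PhCN,191,24 h,Reflux,68
4,PdCl2,2,Acetic acid,RT,15 m,Stirring,0
5,PdCl2,"2,5",Acetic acid,RT,15 m,Stirring,0
6,PdCl2,"2,5",Acetic acid,RT,30 m,Stirring,10
7,PdCl2,3,Acetic acid,RT,30 m,Stirring,15
8,PdCl2,3,Acetic acid,RT,24 h,Stirring,20
9,Pd(OAc)2,"2,5",Acetic acid,RT,30 m,Stirring,5
10,Pd(OAc)2,3,Acetic acid,RT,30 m,Stirring,5
11,Pd(OAc)2,3,Chloroform-Methanol,70,45 m,Stirring,24
12,Pd(acac)2,3,PhCN,191,15 m,MW,0
13,Pd(acac)2,3,DMF,153,15 m,MW,0
14,Pd(acac)2,3,Pyridine,180,15 m,Reflux,0
15,Pd(acac)2,3,Pyridine,180,45 m,Reflux,0
16,Pd(acac)2,3,Pyridine,180,24 h,Reflux,49
17,Pd(acac)2,3,NMP,180,15 m,MW,81
18,PtCl2,3,PhCN,191,24 h,Reflux,0
19,Pt(acac)2,3,PhCN,191,24 h,Reflux,23
20,Pt(acac)2,3,PhCN,191,15 m,MW,0
21,Pt(acac)2,3,PhCN,191,45 m,MW,0
22,Pt(acac)2,3,Chloroform-Methanol,70,45 m,Reflux,0
23,Pt(acac)2,3,Chloroform-Methanol,70,24 h,Reflux,0
24,Pt(acac)2,3,NMP,110,45 m,MW,25
25,K2PtCl4,3,NMP,110,45 m,MW,0
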