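rank,alternative,phi_net,phi_plus,phi_minus
1,Microfluidics,0.2182,0.2194,0.0012
2,Biosensor,0.1925,0.1998,0.0073
3,FISH,0.1337,0.1658,0.0321
4,Real-time microscopy systems,0.0808,0.1595,0.0787
5,Urine flow cytometry,0.0651,0.1419,0.0768
6,Chromogenic agar,0.0569,0.1565,0.0997
7,MALDI-TOF-MS,0.0364,0.1269,0.0905
8,Multiplex PCR,-0.0087,0.1091,0.1178
9,Conventional culture,-0.0241,0.0992,0.1233
10,Catalase,-0.0282,0.1032,0.1314
11,Sequence-based diagnostics,-0.0311,0.1067,0.1378
12,Immunologically based assay,-0.1112,0.0733,0.1845
13,Nitrite,-0.1212,0.0702,0.1914
14,Combined LE and nitrite,-0.1335,0.0563,0.1899
15,Microscopy,-0.1513,0.0580,0.2093
16,Leucocyte esterase,-0.1743,0.0439,0.2182
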