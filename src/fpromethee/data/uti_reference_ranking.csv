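rank,alternative,phi_net,phi_plus,phi_minus
1,Biosensor,0.0063,0.0064,0.0001
2,Real-time microscopy systems,0.0030,0.0041,0.0011
3,Catalase,0.0026,0.0040,0.0014
4,Combined LE and nitrite,0.0025,0.0039,0.0014
5,Immunologically based assay,0.0020,0.0031,0.0011
6,Microfluidics,0.0019,0.0031,0.0012
7,Nitrite,0.0018,0.0039,0.0021
8,Leucocyte esterase,0.0018,0.0039,0.0021
9,Conventional culture,0.0004,0.0038,0.0034
10,Chromogenic agar,-0.0021,0.0025,0.0045
11,Microscopy,-0.0022,0.0013,0.0035
12,FISH,-0.0029,0.0012,0.0041
13,MALDI-TOF-MS,-0.0030,0.0011,0.0042
14,Multiplex PCR,-0.0036,0.0013,0.0049
15,Urine flow cytometry,-0.0037,0.0008,0.0045
16,Sequence-based diagnostics,-0.0048,0.0029,0.0077
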