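dataset,GraphProt,mDBN-,mDBN+
ALKBH5 PAR-CLIP,0.680,0.686,0.714
C17ORF85 PAR-CLIP,0.800,0.817,0.820
C22ORF28 PAR-CLIP,0.751,0.783,0.792
CAPRIN1 PAR-CLIP,0.855,0.825,0.834
Ago2 HITS-CLIP,0.765,0.805,0.809
ELAVL1 HITS-CLIP,0.955,0.964,0.966
SFRS1 HITS-CLIP,0.898,0.927,0.931
HNRNPC iCLIP,0.952,0.961,0.962
TDP43 iCLIP,0.874,0.874,0.876
TIA1 iCLIP,0.861,0.888,0.891
TIAL1 iCLIP,0.833,0.867,0.870
Ago1-4 PAR-CLIP,0.895,0.872,0.881
ELAVL1 PAR-CLIP (B),0.935,0.956,0.961
ELAVL1 PAR-CLIP (A),0.959,0.965,0.966
EWSR1 PAR-CLIP,0.935,0.964,0.966
FUS PAR-CLIP,0.968,0.979,0.980
ELAVL1 PAR-CLIP (C),0.991,0.994,0.994
IGF2BP1-3 PAR-CLIP,0.889,0.872,0.879
MOV10 PAR-CLIP,0.863,0.831,0.854
PUM2 PAR-CLIP,0.954,0.965,0.971
QKI PAR-CLIP,0.957,0.981,0.983
TAF15 PAR-CLIP,0.970,0.980,0.983
PTB HITS-CLIP,0.937,0.879,0.983
ZC3H7B PAR-CLIP,0.820,0.786,0.796
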