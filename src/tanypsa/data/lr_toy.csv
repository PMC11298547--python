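ligand,receptor,annotation,pathway
Ptn,Sdc4,Secreted Signaling,PTN
Ptn,Ptprz1,Secreted Signaling,PTN
Mdk,Sdc2,Secreted Signaling,MK
Bmp4,Bmpr1a_Bmpr2,Secreted Signaling,BMP
Bmp7,Bmpr1b_Acvr2a,Secreted Signaling,BMP
Fgf1,Fgfr1,Secreted Signaling,FGF
Fgf2,Fgfr3,Secreted Signaling,FGF
Igf1,Igf1r,Secreted Signaling,IGF
Vegfa,Flt1,Secreted Signaling,VEGF
Wnt5a,Fzd3,Secreted Signaling,ncWNT
Fn1,Itga5_Itgb1,ECM-Receptor,FN1
Fn1,Sdc1,ECM-Receptor,FN1
Col1a1,Itga1_Itgb1,ECM-Receptor,COLLAGEN
Col4a1,Itga2_Itgb1,ECM-Receptor,COLLAGEN
Lama2,Dag1,ECM-Receptor,LAMININ
Lamb1,Itga6_Itgb1,ECM-Receptor,LAMININ
Lamc1,Itga7_Itgb1,ECM-Receptor,LAMININ
Spp1,Cd44,ECM-Receptor,SPP1
Thbs1,Itga3_Itgb1,ECM-Receptor,THBS
Tnc,Itga9_Itgb1,ECM-Receptor,TENASCIN
Nrxn1,Nlgn1,Cell-Cell Contact,NRXN
Nrxn1,Nlgn2,Cell-Cell Contact,NRXN
Nrxn1,Nlgn3,Cell-Cell Contact,NRXN
Cdh2,Cdh2r,Cell-Cell Contact,CDH
Ncam1,Ncam2,Cell-Cell Contact,NCAM
Efna5,Epha4,Cell-Cell Contact,EPHA
Efnb2,Ephb1,Cell-Cell Contact,EPHB
Dll1,Notch1,Cell-Cell Contact,NOTCH
Jam2,Jam3,Cell-Cell Contact,JAM
Cadm1,Cadm3,Cell-Cell Contact,CADM
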