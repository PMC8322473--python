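patient_id,gene,cdna,protein,preop_nra,preop_depth,preop_vaf_pct,preop_z,postop_nra,postop_depth,postop_vaf_pct,postop_z
P2,KRAS,c.181C>A,p.Q61K,25,7896,0.32,7.3,,,,
P2,KRAS,c.38G>A,p.G13D,127,7999,1.59,100.0,,,,
P3,KRAS,c.35G>A,p.G12D,29,11423,0.25,14.4,31,8914,0.35,18.2
P3,SMAD4,c.1082G>A,p.R361H,26,12303,0.21,6.0,16,9927,0.16,4.4
P3,TP53,c.586C>T,p.R196X,41,11576,0.35,33.8,28,9681,0.29,27.2
P7,KRAS,c.38G>A,p.G13D,59,5698,1.04,100.0,,,,
P12,ALK,c.3257C>T,p.S1086L,9,11762,0.08,6.3,,,,
P14,KRAS,c.34G>C,p.G12R,14,8746,0.16,100.0,10,9863,0.10,100.0
P14,TP53,c.844C>T,p.R282W,19,11036,0.17,4.5,40,11909,0.34,9.6
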