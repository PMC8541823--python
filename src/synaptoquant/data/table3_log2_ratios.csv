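gene_symbol,flybase_id,log2_R1,log2_R2,log2_R3
ATP6AP2,FBgn0037671,6.154281057,9.481786693,5.17436482
Vha100-1,FBgn0028671,1.499248537,8.012982519,5.43599503
VhaAC39-1,FBgn0028665,2.104797507,8.293264658,4.86741949
CG31030,FBgn0051030,3.669278876,7.960835791,"5,19465574"
Twdlβ,FBgn0033658,1.642952792,3.068640973,2.35207192
Ccp84Ag,FBgn0004777,1.543972087,1.326485589,1.86392045
CG13627,FBgn0039217,5.738384187,4.008318188,3.18433108
mfas,FBgn0260745,1.596554441,3.368384477,3.03376685
CG16820,FBgn0032495,4.77051909,9.784086057,3.60280541
Cpr64Ab,FBgn0035511,1.08994458,2.758609792,2.31103817
CG14752,FBgn0033307,2.21698759,3.69458382,3.10154816
CG15615,FBgn0034159,2.77101281,5.12362053,3.39808341
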