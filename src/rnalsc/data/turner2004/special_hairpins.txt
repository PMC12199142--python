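# special hairpin loops: closing pair + loop sequence, dG(37C) in 0.01 kcal/mol
CAACG 680
GUUAC 690
CAACGG 550
CCAAGG 330
CCACGG 370
CCCAGG 340
CCGAGG 350
CCGCGG 360
CCUAGG 370
CCUCGG 250
CUAAGG 360
CUACGG 280
CUCAGG 370
CUCCGG 270
CUGCGG 280
CUUAGG 350
CUUCGG 370
CUUUGG 370
ACAGUACU 280
ACAGUGAU 360
ACAGUGCU 290
ACAGUGUU 180
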