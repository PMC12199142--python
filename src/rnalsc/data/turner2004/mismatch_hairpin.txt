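# mismatch_hairpin dG(37C), 0.01 kcal/mol; 7x5x5 row-major over pair order CG GC GU UG AU UA NN, base order N A C G U
-80 -100 -110 -100 -80 -140 -150 -150 -140 -150 -80 -100 -110 -100 -80 -150
-230 -150 -240 -150 -100 -100 -140 -100 -210 -50 -110 -70 -110 -50 -110 -110
-150 -130 -150 -50 -110 -70 -110 -50 -150 -250 -150 -220 -150 -100 -110 -100
-110 -160 20 20 -20 -10 -20 20 20 -50 -30 -50 -10 -10 -20 -10
-20 -50 -100 -50 -110 -50 -10 -10 -30 -10 -100 0 -20 -10 -20 0
-30 -50 -30 -60 -30 0 -20 -10 -20 0 -30 -90 -30 -110 -30 -10
-20 -10 -20 -90 -10 -10 -20 -10 -20 -30 -30 -50 -30 -50 -10 -10
-20 -10 -20 -50 -120 -50 -110 -50 -10 -10 -30 -10 -120 0 -20 -10
-20 0 -30 -50 -30 -50 -30 0 -20 -10 -20 0 -30 -150 -30 -150
-30 -10 -20 -10 -20 -90 20 20 -10 -10 0 20 20 -30 -30 -30
0 -10 -10 -10 0 -30 -90 -30 -110 -30 -10 -10 -10 -10 -90
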