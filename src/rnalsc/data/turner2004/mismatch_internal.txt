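# mismatch_internal dG(37C), 0.01 kcal/mol; 7x5x5 row-major over pair order CG GC GU UG AU UA NN, base order N A C G U
0 0 0 0 0 0 0 0 -80 0 0 0 0 0 0 0
-100 0 -100 0 0 0 0 0 -60 0 0 0 0 0 0 0
0 -80 0 0 0 0 0 0 0 -100 0 -100 0 0 0 0
0 -60 70 70 70 70 70 70 70 70 -10 70 70 70 70 70
70 70 -30 70 -30 70 70 70 70 70 10 70 70 70 70 70
70 70 70 -10 70 70 70 70 70 70 70 -30 70 -30 70 70
70 70 70 10 70 70 70 70 70 70 70 70 -10 70 70 70
70 70 70 70 -30 70 -30 70 70 70 70 70 10 70 70 70
70 70 70 70 70 -10 70 70 70 70 70 70 70 -30 70 -30
70 70 70 70 70 10 70 70 70 70 70 70 70 70 -10 70
70 70 70 70 70 70 -30 70 -30 70 70 70 70 70 10
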