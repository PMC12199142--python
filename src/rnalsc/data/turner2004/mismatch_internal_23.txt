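# mismatch_internal_23 dG(37C), 0.01 kcal/mol; 7x5x5 row-major over pair order CG GC GU UG AU UA NN, base order N A C G U
0 0 0 0 0 0 0 0 -50 0 0 0 0 0 0 0
-110 0 -70 0 0 0 0 0 -30 0 0 0 0 0 0 0
0 0 0 0 0 0 0 0 0 -120 0 -70 0 0 0 0
0 -30 70 70 70 70 70 70 70 70 70 70 70 70 70 70
70 70 -40 70 0 70 70 70 70 70 40 70 70 70 70 70
70 70 70 20 70 70 70 70 70 70 70 -40 70 0 70 70
70 70 70 40 70 70 70 70 70 70 70 70 70 70 70 70
70 70 70 70 -40 70 0 70 70 70 70 70 40 70 70 70
70 70 70 70 70 20 70 70 70 70 70 70 70 -40 70 0
70 70 70 70 70 40 70 70 70 70 70 70 70 70 70 70
70 70 70 70 70 70 -40 70 0 70 70 70 70 70 40
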