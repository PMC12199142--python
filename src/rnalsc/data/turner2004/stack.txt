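# stack dG(37C), 0.01 kcal/mol; 7x7 row-major over pair order CG GC GU UG AU UA NN
-240 -330 -210 -140 -210 -210 -140 -330 -340 -250 -150 -220 -240 -150 -210 -250
130 -50 -140 -130 130 -140 -150 -50 30 -60 -100 30 -210 -220 -140 -60
-110 -90 -60 -210 -240 -130 -100 -90 -130 -90 -140 -150 130 30 -60 -90
130
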