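# 1x1 internal loop dG(37C), 0.01 kcal/mol; 7x7x5x5 row-major (pair1, pair2, X, Y)
90 90 50 50 50 90 90 50 50 50 50 50 50 50 50 50
50 50 -140 50 50 50 50 50 40 90 90 50 50 60 90 90
-40 50 50 60 30 50 50 60 50 -10 50 -220 50 50 50 0
50 -10 120 120 120 120 120 120 60 50 120 120 120 120 120 120
120 120 -20 120 -140 120 120 120 100 120 110 220 220 170 120 120
220 220 130 120 120 170 120 170 120 120 120 120 120 -140 120 120
120 120 120 110 120 120 120 120 120 120 120 120 120 120 120 120
120 120 120 120 120 120 -140 120 120 120 120 120 80 120 120 120
120 120 120 120 120 120 120 120 120 120 120 120 120 120 120 -140
120 120 120 120 120 120 220 220 170 120 120 220 220 130 120 120
170 120 170 120 120 120 120 120 -140 120 120 120 120 120 120 90
90 60 50 50 90 90 30 -10 50 50 -40 50 50 0 50 50
50 -220 50 60 50 60 50 -10 80 80 50 50 50 80 80 50
50 50 50 50 50 50 50 50 50 50 -230 50 50 50 50 50
-60 190 190 120 150 150 190 190 120 150 120 120 120 120 120 120
120 120 120 -140 120 150 120 120 120 150 160 160 120 120 120 160
160 120 100 120 120 120 120 120 120 120 120 120 -140 120 120 120
120 120 70 120 120 120 120 120 120 120 120 120 120 120 120 120
120 120 120 120 120 -140 120 120 120 120 120 80 120 120 120 120
120 120 120 120 120 120 120 120 120 120 120 120 120 120 -140 120
120 120 120 120 120 190 190 120 150 150 190 190 120 150 120 120
120 120 120 120 120 120 120 -140 120 150 120 120 120 150 120 120
120 120 120 120 60 120 -20 120 120 50 120 120 100 120 120 120
-140 120 120 120 120 120 110 190 190 120 120 150 190 190 120 120
120 120 120 120 120 120 150 150 120 -140 120 150 120 120 120 150
190 190 190 190 190 190 190 190 190 190 190 190 190 190 190 190
190 190 -70 190 190 190 190 190 120 190 190 190 190 190 190 190
190 190 190 190 190 190 190 190 190 190 190 -70 190 190 190 190
190 160 190 190 190 190 190 190 190 190 190 190 190 190 190 190
190 190 190 190 -70 190 190 190 190 190 120 190 190 190 190 190
190 190 190 190 190 190 190 190 190 190 190 190 190 -70 190 190
190 190 190 160 190 190 190 190 190 190 190 190 190 190 190 190
190 190 190 190 190 190 -70 190 190 190 190 190 160 220 220 170
120 120 220 220 120 120 120 170 130 170 120 120 120 120 120 -140
120 120 120 120 120 110 160 160 120 120 120 160 160 120 120 120
120 120 120 120 120 120 100 120 -140 120 120 120 120 120 70 190
190 190 190 190 190 190 190 190 190 190 190 190 190 190 190 190
190 -70 190 190 190 190 190 160 190 190 190 190 190 190 190 190
190 190 190 190 190 190 190 190 190 190 -70 190 190 190 190 190
190 190 190 190 190 190 190 190 190 190 190 190 190 190 190 190
190 190 190 -70 190 190 190 190 190 160 190 190 190 190 190 190
190 190 190 190 190 190 190 190 190 190 190 190 -70 190 190 190
190 190 190 220 220 190 190 190 220 220 190 190 190 190 190 190
190 190 190 190 190 -70 190 190 190 190 190 190 120 120 120 120
120 120 120 120 120 120 120 120 120 120 120 120 120 120 -140 120
120 120 120 120 80 120 120 120 120 120 120 120 120 120 120 120
120 120 120 120 120 120 120 -140 120 120 120 120 120 80 190 190
190 190 190 190 190 190 190 190 190 190 190 190 190 190 190 190
-70 190 190 190 190 190 120 190 190 190 190 190 190 190 190 190
190 190 190 190 190 190 190 190 190 -70 190 190 190 190 190 160
190 190 190 190 190 190 190 190 190 190 190 190 190 190 190 190
190 190 -70 190 190 190 190 190 120 190 190 190 190 190 190 190
190 190 190 190 190 190 190 190 190 190 190 -70 190 190 190 190
190 150 190 190 190 190 190 190 190 190 190 190 190 190 190 190
190 190 190 190 -70 190 190 190 190 190 160 120 120 120 120 120
120 120 120 120 120 120 120 120 120 120 120 120 120 -140 120 120
120 120 120 120 120 120 120 120 120 120 120 120 120 120 120 120
120 120 120 120 120 120 -140 120 120 120 120 120 120 190 190 190
190 190 190 190 190 190 190 190 190 190 190 190 190 190 190 -70
190 190 190 190 190 160 190 190 190 190 190 190 190 190 190 190
190 190 190 190 190 190 190 190 -70 190 190 190 190 190 190 190
190 190 190 190 190 190 190 190 190 190 190 190 190 190 190 190
190 -70 190 190 190 190 190 150 190 190 190 190 190 190 190 190
190 190 190 190 190 190 190 190 190 190 -70 190 190 190 190 190
170 190 190 190 190 190 190 190 190 190 190 190 190 190 190 190
190 190 190 -70 190 190 190 190 190 190 220 220 170 120 120 220
220 120 120 120 170 130 170 120 120 120 120 120 -140 120 120 120
120 120 120 190 190 120 120 150 190 190 120 120 120 120 120 120
120 120 150 150 120 -140 120 150 120 120 120 150 190 190 190 190
190 190 190 190 190 190 190 190 190 190 190 190 190 190 -70 190
190 190 190 190 160 220 220 190 190 190 220 220 190 190 190 190
190 190 190 190 190 190 190 -70 190 190 190 190 190 190 190 190
190 190 190 190 190 190 190 190 190 190 190 190 190 190 190 190
-70 190 190 190 190 190 160 190 190 190 190 190 190 190 190 190
190 190 190 190 190 190 190 190 190 -70 190 190 190 190 190 190
220 220 190 190 190 220 220 190 190 190 190 190 190 190 190 190
190 190 -70 190 190 190 190 190 190
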