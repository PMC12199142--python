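# loop initiation dG(37C), 0.01 kcal/mol; three rows of 31 values (sizes 0..30): hairpin, bulge, internal; 1000000000 = undefined
1000000000 1000000000 1000000000 540 560 570 540 600 550 640 650 660 670 680 690 690 700 710 710 720 720 730 730 740 740 750 750 750 760 760 770
1000000000 380 280 320 360 400 440 460 470 480 490 500 510 520 530 540 540 550 550 560 570 570 580 580 580 590 590 600 600 600 610
1000000000 1000000000 100 100 110 200 200 210 230 240 250 260 270 280 290 290 300 310 310 320 330 330 340 340 350 350 350 360 360 370 370
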