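# misc dG(37C), 0.01 kcal/mol
ninio 60
ninio_max 300
terminal_au 50
lxc 107.856
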