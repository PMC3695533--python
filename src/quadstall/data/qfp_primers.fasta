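>wild-type 69-nt antisense primer carrying the wild-type QFP sequence
TTTTTTAGACCCCACTTCACCCCTGCCCTCCCCATCTTTACCTAAATGAATTTTTTTATTAATAAATAA
>A-mutant 69-nt antisense primer carrying the A-mutant QFP sequence
TTTTTTAGATCCTACTTCACCTCTGCCTTCTCCATCTTTACCTAAATGAATTTTTTTATTAATAAATAA
>C-mutant 69-nt antisense primer carrying the C-mutant QFP sequence
TTTTTTAGACCCGACTTCACCCCTGCCCTCCCCATCTTTACCTAAATGAATTTTTTTATTAATAAATAA
>G-mutant 69-nt antisense primer carrying the G-mutant QFP sequence
TTTTTTAGACCCCACTTCCCCCCTCCCCTCCCCATCTTTACCTAAATGAATTTTTTTATTAATAAATAA
>U-mutant 69-nt antisense primer carrying the U-mutant QFP sequence
TTTTTTAGAACCAACTTCACCCCTGCCCTCACCATCTTTACCTAAATGAATTTTTTTATTAATAAATAA
>first-template 49-nt first-step template without the QFP insert
TAAATGAATTTTTTTATTAATAAATAAGATTTCATAGAAAGCATTTTGT
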