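# Fluorophore-quencher reporter panel: DNA/RNA chimeric oligonucleotides.
# rna_mask flags each nucleotide as D (DNA) or R (RNA backbone).
name	sequence	rna_mask
DR-14-UACA	AAAAAUACAAAAAA	DDDDDRRRRDDDDD
DR-14-UACC	AAAAAUACCAAAAA	DDDDDRRRRDDDDD
DR-14-UACU	AAAAAUACUAAAAA	DDDDDRRRRDDDDD
DR-14-AACA	AAAAAAACAAAAAA	DDDDDRRRRDDDDD
D-13-AAA	AAAAAAAAAAAAA	DDDDDDDDDDDDD
R-13-GUUGU	GUUGUCAUGCCGG	RRRRRRRRRRRRR
R-13-UCUCG	UCUCGGUGCGUUG	RRRRRRRRRRRRR
R-13-UGACA	UGACACGAACCGC	RRRRRRRRRRRRR
DR-14-CACA	AAAAACACAAAAAA	DDDDDRRRRDDDDD
DR-14-UAUA	AAAAAUAUAAAAAA	DDDDDRRRRDDDDD
DR-13-ACA	AAAAAACAAAAAA	DDDDDRRRDDDDD
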