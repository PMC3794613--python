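# Synthetic mammalian-like cytoplasmic tRNA isoacceptor decoding set (48 members).
# Constructed to mirror the size and anticodon repertoire of a gtRNAdb
# mammalian species table; gene counts are plausible placeholders, not
# measurements from any genome.
amino_acid	anticodon	gene_count
Ala	AGC	25
Ala	CGC	5
Ala	UGC	9
Ala	GGC	1
Arg	ACG	7
Arg	CCG	4
Arg	UCG	6
Arg	CCU	5
Arg	UCU	6
Asn	GUU	27
Asp	GUC	15
Cys	GCA	28
Gln	CUG	20
Gln	UUG	11
Glu	CUC	12
Glu	UUC	13
Gly	GCC	14
Gly	CCC	8
Gly	UCC	9
His	GUG	11
Ile	AAU	14
Ile	GAU	1
Ile	UAU	5
Leu	AAG	11
Leu	CAG	9
Leu	UAG	3
Leu	CAA	7
Leu	UAA	4
Lys	CUU	16
Lys	UUU	17
Met	CAU	10
Phe	GAA	12
Pro	AGG	10
Pro	CGG	4
Pro	UGG	7
Ser	AGA	11
Ser	CGA	4
Ser	UGA	5
Ser	GCU	8
Thr	AGU	10
Thr	CGU	6
Thr	UGU	6
Trp	CCA	7
Tyr	GUA	13
Val	AAC	11
Val	CAC	16
Val	UAC	5
Val	GAC	1
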