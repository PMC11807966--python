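name	family	peptide	toxicity_class	canonical	novel
DQ2.5-glia-α1a	GLIA_A1	PFPQPQLPY	T	1	0
DQ2.5-glia-α1b	GLIA_A1	PYPQPQLPY	T	1	0
DQ2.5-glia-α1 (var1)	GLIA_A1	PFLQPQLPY	UNK	0	0
DQ2.5-glia-α1a (var2)	GLIA_A1	PFPQPQLSY	NT	0	0
DQ2.5-glia-α1 (var3)	GLIA_A1	PFSQPQLPY	RT	0	0
DQ2.5-glia-α1a (var4)	GLIA_A1	PFPQPQLPH	UNK	0	0
DQ2.5-glia-α1 (var5)	GLIA_A1	PFPQLQLPY	RT	0	0
DQ2.5-glia-α1a (var6)	GLIA_A1	PFPQPPLPY	UNK	0	0
DQ2.5-glia-α1a (var7)	GLIA_A1	PFPQLQQPY	UNK	0	0
DQ2.5-glia-α1b (var8)	GLIA_A1	PYPQPQLFP	UNK	0	0
DQ2.5-glia-α1b (var9)	GLIA_A1	PYPQPHLPY	UNK	0	0
DQ2.5-glia-α2	GLIA_A2	PQPQLPYPQ	T	1	0
DQ2.5-glia-α2 (var1)	GLIA_A2	PQPQLPYSQ	NT	0	0
DQ2.5-glia-α2 (var2)	GLIA_A2	SQPQLPYSQ	NT	0	0
DQ2.5-glia-α2 (var3)	GLIA_A2	PQPQLSYSQ	NT	0	0
DQ2.5-glia-α2 (var4)	GLIA_A2	PQLQLPYPQ	RT	0	0
DQ2.5-glia-α2 (var5)	GLIA_A2	LQPQLPYSQ	UNK	0	0
DQ2.5-glia-α2 (var6)	GLIA_A2	FPPQLPYPQ	NT	0	0
DQ2.5-glia-α2 (var7)	GLIA_A2	FLPQLPYPQ	STAR_NT	0	0
DQ2.5-glia-α2 (var8)	GLIA_A2	PQPQLPYLQ	RT	0	0
DQ2.5-glia-α2 (var9)	GLIA_A2	PQPQLPYSH	NT	0	0
DQ2.5-glia-α2 (var10)	GLIA_A2	PQPHLPYPQ	STAR_NT	0	0
DQ2.5-glia-α2 (var11)	GLIA_A2	PQPQPQYPQ	UNK	0	0
DQ2.5-glia-α2 (var12)	GLIA_A2	PQPQYPQPQ	UNK	0	0
DQ2.5-glia-α2 (var13)	GLIA_A2	PQPQLPHSQ	UNK	0	0
DQ2.5-glia-α2 (var14)	GLIA_A2	SQPQLPYLQ	UNK	0	0
DQ2.5-glia-α2 (var15)	GLIA_A2	LQPQLPYPQ	UNK	0	1
DQ2.5-glia-α2 (var16)	GLIA_A2	PQPPLPYPQ	UNK	0	1
DQ2.5-glia-α2 (var17)	GLIA_A2	PQPQLPYHQ	UNK	0	1
DQ2.5-glia-α3	GLIA_A3	FRPQQPYPQ	T	1	0
DQ2.5-glia-α3 (var1)	GLIA_A3	FPPQQPYPQ	NT	0	0
DQ2.5-glia-α3 (var2)	GLIA_A3	FSPQQPYPQ	UNK	0	0
DQ2.5-glia-α3 (var3)	GLIA_A3	FLPQQPYPQ	RT	0	0
DQ2.5-glia-α3 (var4)	GLIA_A3	FPQQQPYPQ	STAR_T	0	0
DQ2.5-glia-α3 (var5)	GLIA_A3	FPPQQSYPQ	NT	0	0
DQ2.5-glia-α3 (var6)	GLIA_A3	FQPQQPYPQ	UNK	0	0
DQ2.5-glia-α3 (var7)	GLIA_A3	FRPQQSYPQ	RT	0	0
DQ2.5-glia-α3 (var8)	GLIA_A3	FPPQQPYPH	NT	0	0
DQ2.5-glia-α3 (var9)	GLIA_A3	FPPQQPYLQ	NT	0	0
DQ2.5-glia-α3 (var10)	GLIA_A3	FRPQKPYPQ	STAR_T	0	0
DQ2.5-glia-α3 (var11)	GLIA_A3	FRQQQPYPQ	RT	0	0
DQ2.5-glia-α3 (var12)	GLIA_A3	FPPQQPYTQ	NT	0	0
DQ2.5-glia-α3 (var13)	GLIA_A3	FRPQQLYPQ	UNK	0	0
DQ2.5-glia-α3 (var14)	GLIA_A3	FRPQQPFPQ	UNK	0	1
p31-41	P31_43	PGQQQPFPPQQPY	T	1	0
P31-43 (var1)	P31_43	LGQQQPFPPQQPY	UNK	0	0
P31-43 (var2)	P31_43	LGQQQQFPPQQPY	UNK	0	0
P31-43 (var3)	P31_43	LGQQQPFRPQQPY	UNK	0	0
P31-43 (var4)	P31_43	LGQ*QPFPPQQPY	UNK	0	0
P31-43 (var5)	P31_43	LGQQQSFPPQQPY	UNK	0	0
P31-43 (var6)	P31_43	PGQQQPFPPQQPYPQPQPF	T	0	0
P31-43 (var7)	P31_43	PGQQQPFPPQQPYPQPQPFPSQQPY	T	0	0
DQ2.5-glia-α (44-55)	OTHER	PQPQPFPSQQPY	T	0	0
DQ2.5-glia-α (51-70)	OTHER	SQQPYLQLQPFPQPQLPY	T	0	0
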