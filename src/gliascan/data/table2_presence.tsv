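name	L1	L2	L3	L4	L5	L6	L7	L8
DQ2.5-glia-α1a	1	1	1	1	1	1	1	1
DQ2.5-glia-α1b	1	1	1	1	1	1	1	1
DQ2.5-glia-α1 (var1)	1	1	1	1	1	1	1	1
DQ2.5-glia-α1a (var2)	1	1	1	1	1	1	1	1
DQ2.5-glia-α1 (var3)	1	1	1	1	1	1	1	1
DQ2.5-glia-α1a (var4)	0	0	0	1	0	0	0	0
DQ2.5-glia-α1 (var5)	0	0	1	0	0	1	0	1
DQ2.5-glia-α1a (var6)	0	0	1	0	0	0	0	0
DQ2.5-glia-α1a (var7)	0	0	0	0	0	0	0	1
DQ2.5-glia-α1b (var8)	1	0	0	1	0	0	1	1
DQ2.5-glia-α1b (var9)	1	1	1	1	1	1	1	1
DQ2.5-glia-α2	1	1	1	1	1	1	1	1
DQ2.5-glia-α2 (var1)	1	1	1	1	1	1	1	1
DQ2.5-glia-α2 (var2)	1	1	1	1	1	1	1	1
DQ2.5-glia-α2 (var3)	1	1	1	1	1	1	1	1
DQ2.5-glia-α2 (var4)	0	0	1	0	0	1	0	1
DQ2.5-glia-α2 (var5)	1	1	1	1	1	1	1	1
DQ2.5-glia-α2 (var6)	1	1	1	1	1	1	1	1
DQ2.5-glia-α2 (var7)	1	1	1	1	1	1	1	1
DQ2.5-glia-α2 (var8)	1	1	1	1	1	1	1	1
DQ2.5-glia-α2 (var9)	1	0	0	1	0	0	1	1
DQ2.5-glia-α2 (var10)	1	1	1	1	1	1	1	1
DQ2.5-glia-α2 (var11)	1	1	1	1	1	1	1	1
DQ2.5-glia-α2 (var12)	1	1	1	1	1	1	1	1
DQ2.5-glia-α2 (var13)	0	0	0	1	0	0	0	0
DQ2.5-glia-α2 (var14)	1	1	1	1	1	1	1	1
DQ2.5-glia-α2 (var15)	1	1	0	1	0	0	1	1
DQ2.5-glia-α2 (var16)	0	0	1	0	0	0	0	0
DQ2.5-glia-α2 (var17)	1	0	0	0	1	1	0	0
DQ2.5-glia-α3	1	1	1	1	1	1	1	1
DQ2.5-glia-α3 (var1)	1	1	1	1	1	1	1	1
DQ2.5-glia-α3 (var2)	1	1	1	1	1	1	1	1
DQ2.5-glia-α3 (var3)	0	0	0	1	0	0	1	0
DQ2.5-glia-α3 (var4)	1	1	1	1	1	1	1	1
DQ2.5-glia-α3 (var5)	1	1	1	1	1	1	1	1
DQ2.5-glia-α3 (var6)	0	0	0	0	0	0	0	1
DQ2.5-glia-α3 (var7)	1	1	1	1	1	1	1	1
DQ2.5-glia-α3 (var8)	1	1	1	1	1	1	1	1
DQ2.5-glia-α3 (var9)	1	1	1	1	1	1	1	1
DQ2.5-glia-α3 (var10)	0	0	0	0	0	0	0	1
DQ2.5-glia-α3 (var11)	0	0	0	0	0	0	0	1
DQ2.5-glia-α3 (var12)	0	0	0	0	0	0	1	1
DQ2.5-glia-α3 (var13)	1	1	1	1	1	1	1	1
DQ2.5-glia-α3 (var14)	1	1	1	1	1	1	1	1
p31-41	1	1	1	1	1	1	1	1
P31-43 (var1)	1	1	1	1	1	1	1	1
P31-43 (var2)	1	1	1	1	1	1	1	1
P31-43 (var3)	1	1	1	1	1	1	1	1
P31-43 (var4)	1	1	1	1	1	1	1	1
P31-43 (var5)	1	1	1	1	1	1	1	1
P31-43 (var6)	1	1	1	1	1	1	1	1
P31-43 (var7)	1	1	1	1	1	1	1	1
DQ2.5-glia-α (44-55)	1	1	1	1	1	1	1	1
DQ2.5-glia-α (51-70)	1	1	1	1	1	1	1	1
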