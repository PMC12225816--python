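element	mass_number	bone	bone_marrow
H	1	3.50	10.50
C	12	16.00	41.40
N	14	4.20	3.40
O	16	44.50	43.90
Na	23	0.30	0.10
Mg	24	0.20	0.20
P	31	9.50	0.20
S	32	0.30	0.20
Ca	40	21.50	0.00
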