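age_group	bone_density	marrow_density
newborn	1.65	1.0
1y	1.70	1.0
5y	1.80	1.0
10y	1.83	1.0
15y	1.85	1.0
adult	1.90	0.98
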