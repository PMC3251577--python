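pos	A	C	G	T
-3	0.33	0.37	0.18	0.12
-2	0.60	0.13	0.14	0.13
-1	0.08	0.04	0.81	0.07
1	0.001	0.001	0.997	0.001
2	0.001	0.001	0.001	0.997
3	0.59	0.03	0.34	0.04
4	0.68	0.09	0.12	0.11
5	0.06	0.05	0.84	0.05
6	0.16	0.17	0.21	0.46
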