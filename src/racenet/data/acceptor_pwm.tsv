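pos	A	C	G	T
-22	0.09	0.31	0.12	0.48
-21	0.09	0.31	0.12	0.48
-20	0.09	0.31	0.12	0.48
-19	0.09	0.31	0.12	0.48
-18	0.09	0.31	0.12	0.48
-17	0.09	0.31	0.12	0.48
-16	0.09	0.31	0.12	0.48
-15	0.09	0.31	0.12	0.48
-14	0.09	0.31	0.12	0.48
-13	0.09	0.31	0.12	0.48
-12	0.09	0.31	0.12	0.48
-11	0.09	0.31	0.12	0.48
-10	0.09	0.31	0.12	0.48
-9	0.09	0.31	0.12	0.48
-8	0.09	0.31	0.12	0.48
-7	0.09	0.31	0.12	0.48
-6	0.09	0.31	0.12	0.48
-5	0.09	0.31	0.12	0.48
-4	0.09	0.31	0.12	0.48
-3	0.24	0.30	0.21	0.25
-2	0.05	0.65	0.03	0.27
-1	0.997	0.001	0.001	0.001
0	0.001	0.001	0.997	0.001
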