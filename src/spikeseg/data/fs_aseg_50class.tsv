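# FreeSurfer-aseg-derived 50-class lookup (raw aseg id -> compact class id).
# Class 0 is background/unknown; raw ids not listed here collapse to 0.
# This is the package default and is user-overridable (--label-map).
0	0
2	1
41	2
3	3
42	4
4	5
43	6
5	7
44	8
7	9
46	10
8	11
47	12
10	13
49	14
11	15
50	16
12	17
51	18
13	19
52	20
17	21
53	22
18	23
54	24
26	25
58	26
28	27
60	28
30	29
62	30
31	31
63	32
14	33
15	34
16	35
24	36
72	37
77	38
80	39
85	40
251	41
252	42
253	43
254	44
255	45
25	46
57	47
29	48
61	49
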