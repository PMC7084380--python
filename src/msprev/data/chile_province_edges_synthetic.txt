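# SYNTHETIC adjacency for the 52 Chilean provinces, 1-based ids.
# This edge list is a hand-made approximation built for exercising the
# spatial machinery on a realistic irregular topology: a north-to-south
# backbone (provinces are numbered roughly north to south) plus lateral
# links between provinces of the same or adjacent administrative regions.
# It makes NO claim to cartographic fidelity.
1	2
2	3
3	4
4	5
5	6
6	7
7	8
8	9
9	10
10	11
11	12
12	13
13	14
14	15
15	16
16	17
17	18
18	19
19	20
20	21
21	22
22	23
23	24
24	25
25	26
26	27
27	28
28	29
29	30
30	31
31	32
32	33
33	34
34	35
35	36
36	37
37	38
38	39
39	40
40	41
41	42
42	43
43	44
44	45
45	46
46	47
47	48
48	49
49	50
50	51
51	52
1	3
5	7
9	11
11	13
14	16
14	17
17	19
20	22
21	23
21	25
24	26
27	29
31	33
34	36
35	37
39	41
42	44
44	46
47	49
50	52
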