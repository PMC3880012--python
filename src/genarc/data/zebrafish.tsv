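# D. rerio Zv9 chromosome lengths (bp)
1	60348388
2	60300536
3	63268876
4	62094675
5	75682077
6	59938731
7	77276063
8	56184765
9	58232459
10	46591166
11	46661319
12	50697278
13	54093808
14	53733891
15	47442429
16	58780683
17	53984731
18	49877488
19	50254551
20	55952140
21	44544065
22	42261000
23	46386876
24	43947580
25	38499472
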