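# O. sativa MSU6 chromosome lengths (bp)
1	43268879
2	35930381
3	36406689
4	35278225
5	29894789
6	31246789
7	29696629
8	28439308
9	23011239
10	23134759
11	28512666
12	27497214
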