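# M. musculus GRCm38 chromosome lengths (bp)
1	195471971
2	182113224
3	160039680
4	156508116
5	151834684
6	149736546
7	145441459
8	129401213
9	124595110
10	130694993
11	122082543
12	120129022
13	120421639
14	124902244
15	104043685
16	98207768
17	94987271
18	90702639
19	61431566
X	171031299
Y	91744698
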