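# S. lycopersicum SL2.40 chromosome lengths (bp)
1	90304244
2	49918294
3	64840714
4	64064312
5	65021438
6	46041636
7	65268621
8	63032657
9	67662091
10	64834305
11	53386025
12	65486253
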