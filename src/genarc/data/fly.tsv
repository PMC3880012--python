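# D. melanogaster BDGP5 chromosome arm lengths (bp)
2L	23011544
2R	21146708
3L	24543557
3R	27905053
4	1351857
X	22422827
Y	3667352
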