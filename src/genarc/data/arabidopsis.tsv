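# A. thaliana TAIR10 chromosome lengths (bp)
1	30427671
2	19698289
3	23459830
4	18585056
5	26975502
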