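# E. coli K-12 MG1655 chromosome length (bp)
chromosome	4641652
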