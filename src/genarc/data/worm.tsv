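# C. elegans WBcel235 chromosome lengths (bp)
I	15072434
II	15279421
III	13783801
IV	17493829
V	20924180
X	17718942
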