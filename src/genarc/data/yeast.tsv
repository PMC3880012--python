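# S. cerevisiae EF4 chromosome lengths (bp)
I	230218
II	813184
III	316620
IV	1531933
V	576874
VI	270161
VII	1090940
VIII	562643
IX	439888
X	745751
XI	666816
XII	1078177
XIII	924431
XIV	784333
XV	1091291
XVI	948066
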