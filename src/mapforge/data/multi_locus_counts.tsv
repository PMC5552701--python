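n_loci	n_assays
2	909
3	11
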