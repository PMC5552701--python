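n_maps	n_markers
1	14931
2	9574
3	3612
4	644
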