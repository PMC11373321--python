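# straight 3-node path, unit segments along z
1 1 0 0 0 1.0 -1
2 3 0 0 1 0.5 1
3 3 0 0 2 0.5 2
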