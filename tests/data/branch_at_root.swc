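# root bifurcates immediately
1 1 0 0 0 1.5 -1
2 3 3 0 0 0.7 1
3 3 -3 0 0 0.7 1
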