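# three stems of two nodes each
1 1 0 0 0 2.0 -1
2 3 5 0 0 1.0 1
3 3 10 0 0 0.8 2
4 3 0 5 0 1.0 1
5 3 0 10 0 0.8 4
6 4 0 0 5 1.0 1
7 4 0 0 10 0.8 6
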