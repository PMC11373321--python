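# axon chain with one branching axon node (index 3)
1 1 0 0 0 2.0 -1
2 2 0 0 5 0.4 1
3 2 0 0 10 0.4 2
4 2 4 0 14 0.3 3
5 2 -4 0 14 0.3 3
6 3 6 0 0 0.8 1
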