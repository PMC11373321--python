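# Y-shaped golden fixture: stem to (0,0,10), two tips at (+-5,0,20)
1 1 0 0 0 1.0 -1
2 3 0 0 10 1.0 1
3 3 5 0 20 1.0 2
4 3 -5 0 20 1.0 2
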