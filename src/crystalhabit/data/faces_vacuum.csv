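hkl,multiplicity,d_hkl,e_att
2 0 0,2,9.16,-250.08
1 1 0,4,8.60,-266.26
0 0 2,2,8.11,-365.24
1 1 -1,4,8.10,-284.40
2 0 -2,2,7.29,-185.29
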