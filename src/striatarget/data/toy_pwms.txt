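ID TOY001
NA planted-site
P0      A      C      G      T
01  12  1  1  1  A
02  1  12  1  1  C
03  1  12  1  1  C
04  12  1  1  1  A
05  1  12  1  1  C
06  12  1  1  1  A
//
ID TOY002
NA ebox
P0      A      C      G      T
01  1  14  1  1  C
02  14  1  1  1  A
03  1  14  1  1  C
04  1  1  14  1  G
05  1  1  1  14  T
06  1  1  14  1  G
//
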