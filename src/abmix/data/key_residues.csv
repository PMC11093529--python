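chain_type,position
H,42
H,49
H,50
H,52
H,54
H,80
H,87
H,105
K,42
K,52
K,53
K,55
K,80
K,82
K,87
K,103
L,42
L,52
L,53
L,55
L,80
L,82
L,87
L,103
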