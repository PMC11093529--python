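chain_type,position
H,2
H,28
H,29
H,30
H,35
H,52
H,53
H,54
H,76
H,78
H,80
H,82
H,87
H,105
H,106
H,118
K,2
K,4
K,41
K,42
K,52
K,53
K,54
K,55
K,80
K,82
K,84
K,85
K,87
K,118
L,2
L,4
L,41
L,42
L,52
L,53
L,54
L,55
L,80
L,82
L,84
L,85
L,87
L,118
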