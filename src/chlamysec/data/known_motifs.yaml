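# Default NeuroPred-style "known motifs" table: mono-/dibasic patterns
# plus spaced variants, over the alphabet {K, R, X} (X = any residue).
# Replace this file (or pass --config) to use a different table.
pc_spacings: [0, 2, 4, 6]
amidation_spacings: [1, 3]
known_motifs: [KR, RR, KK, RK, KXXK, KXXR, RXXK, RXXR]
excluded_motifs: [RK, KXXK, KXXR]
max_basic_tail: 3
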