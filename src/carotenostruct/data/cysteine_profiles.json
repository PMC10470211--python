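{
  "_comment": "Reconstructed (synthetic) cysteine-pattern table for ependymin-related proteins. The published classification defines profiles 1-3 by the number of conserved cysteines and their coarse spacing in the mature chain; the defining alignments are not reproduced here, so these rows are an advisory reconstruction: profile-1 covers the clade-1 four-cysteine arrangement (two disulfide pairs, a short N-terminal Cys-Cys gap followed by a long gap to the C-terminal pair), profiles 2 and 3 the six- and five-cysteine variants. Labels from this table are advisory; counts and positions are always exact.",
  "short_gap_max": 40,
  "profiles": [
    {"name": "profile-1", "count": 4, "gap_classes": ["short", "long", "short"]},
    {"name": "profile-2", "count": 6, "gap_classes": null},
    {"name": "profile-3", "count": 5, "gap_classes": null}
  ]
}
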