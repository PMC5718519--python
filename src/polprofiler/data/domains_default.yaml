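# Default domain boundaries for the archaeal B-family polymerase entries
# (KOD and 9degN share one numbering; chains named A in the deposited files).
# Boundaries are implementer-derived from the deposited models' secondary
# structure and are consistent with the published residue-to-domain
# attributions (D404/D542/E578/E580 palm; R460/Q461/K464/D472/Q483/K487/
# N491/S492 finger).  Override freely: every domain-dependent output echoes
# the ranges it used.
domains:
  5OMF:
    n_terminal: [[A, 1, 129]]
    exonuclease: [[A, 130, 368]]
    beta_hairpin: [[A, 240, 251]]
    palm: [[A, 369, 449], [A, 531, 588]]
    finger: [[A, 450, 530]]
    thumb: [[A, 589, 774]]
  5OMQ:
    n_terminal: [[A, 1, 129]]
    exonuclease: [[A, 130, 368]]
    beta_hairpin: [[A, 240, 251]]
    palm: [[A, 369, 449], [A, 531, 588]]
    finger: [[A, 450, 530]]
    thumb: [[A, 589, 774]]
  5OMV:
    n_terminal: [[A, 1, 129]]
    exonuclease: [[A, 130, 368]]
    beta_hairpin: [[A, 240, 251]]
    palm: [[A, 369, 449], [A, 531, 588]]
    finger: [[A, 450, 530]]
    thumb: [[A, 589, 774]]
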