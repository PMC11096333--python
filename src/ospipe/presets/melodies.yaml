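# Default melody table for the familiar condition.
# Per-note totals across melodies are E=6, F=6, A=6, C=7 per presentation
# cycle; the per-melody split is a documented assumption (only the totals
# are normative).  Unfamiliar melodies are shuffled variants with identical
# target positions and counts.
melodies:
  - melody_id: momiji
    note_counts: {E: 6, C: 2}
    duration_s: 19.2
  - melody_id: harugakita
    note_counts: {F: 1, A: 2, C: 2}
    duration_s: 9.6
  - melody_id: harunoogawa
    note_counts: {F: 5, A: 4}
    duration_s: 19.2
  - melody_id: yuuyakekoyake
    note_counts: {C: 3}
    duration_s: 19.2
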