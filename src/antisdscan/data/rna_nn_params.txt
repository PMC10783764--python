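# RNA:RNA nearest-neighbor free-energy parameters, 37 C.
# Turner/Mathews 1999-style rules. All energies are integers in units of
# 0.01 kcal/mol (centi-kcal). Lines starting with '#' are comments; each
# [block] holds one whitespace-separated table.
#
# Conventions used by the engines in this package:
#   * base-pair order for all pair-indexed tables: CG GC GU UG AU UA
#   * stack[outer][inner]: outer pair is (5'X, 3'W), inner pair is read
#     REVERSED, i.e. for the stack 5'XY3'/3'WZ5' look up stack[XW][ZY].
#   * dangle5/dangle3: rows are the closing pair, columns the dangling
#     base in order A C G U (base 5' / 3' adjacent to the pair).
#   * hairpin/bulge/internal: loop-size-indexed penalties; sizes above 30
#     are extrapolated as value(30) + lxc * ln(size/30).
#   * ninio: internal-loop asymmetry penalty m * |a-b|, capped at max.
#   * terminal_au: per helix-end penalty for AU/GU closing pairs, applied
#     by the intramolecular folding engine only.
#   * helix_end_blunt: per duplex-helix-end term applied when neither
#     strand contributes a dangling nucleotide at that end (both strands
#     end flush with the terminal base pair).
#   * duplex_init: duplex initiation term (zero: the hybridization model
#     is calibrated without an initiation penalty).

[pairs]
CG GC GU UG AU UA

[stack]
  -240    -330    -210    -140    -210    -210
  -330    -340    -250    -150    -220    -240
  -210    -250     130     -50    -140    -130
  -140    -150     -50      30     -60    -100
  -210    -220    -140     -60    -110     -90
  -210    -240    -130    -100     -90    -130

[dangle5]
   -50     -30     -20     -10
   -20     -30       0       0
   -30     -30     -40     -20
   -30     -10     -20     -20
   -30     -30     -40     -20
   -30     -10     -20     -20

[dangle3]
  -110     -40    -130     -60
  -170     -80    -170    -120
   -70     -10     -70     -10
   -80     -50     -80     -60
   -70     -10     -70     -10
   -80     -50     -80     -60

[hairpin]
# sizes 3..30
   570     560     560     540     590     560     640     650     660     670     678     686     694     701     707     713     719     725     730     735     740     744     749     753     757     761     765     769

[bulge]
# sizes 1..30
   380     280     320     360     400     440     459     470     480     490     500     510     519     527     534     541     548     554     560     565     571     576     580     585     589     594     598     602     605     609

[internal]
# sizes 2..30
   410     510     170     180     200     220     230     240     250     260     270     278     286     294     301     307     313     319     325     330     335     340     345     349     353     357     361     365     369

[ninio]
50 300

[lxc]
107.856

[terminal_au]
50

[helix_end_blunt]
45

[duplex_init]
0
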