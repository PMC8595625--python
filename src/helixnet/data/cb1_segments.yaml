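# CB1 receptor segment definition (author/PDB numbering, as in 5XRA/5TGZ).
#
# Authoritative entries, fixed by published residue identities:
#   pivot prolines P358 (TM6) and P394 (TM7);
#   BW anchors implied by the printed pairs N134=1.50, D163=2.50,
#   S203=3.39 (=> 3.50 at 214), E273=5.37 (=> 5.50 at 286),
#   P358=6.50, D390=7.46 / N393=7.49 (=> 7.50 at 394).
#
# The TM first/last residue boundaries below are RECONSTRUCTED approximations
# (the original per-state helix table is not reproduced here); treat them as
# reasonable defaults, not authoritative. The TM4 anchor is likewise marked
# approximate.
segments:
  Nterm: {first: 99, last: 115}
  TM1: {first: 116, last: 145}
  ICL1: {first: 146, last: 149}
  TM2: {first: 150, last: 179}
  ECL1: {first: 180, last: 185}
  TM3: {first: 186, last: 219}
  ICL2: {first: 220, last: 227}
  TM4: {first: 228, last: 252}
  ECL2: {first: 253, last: 266}
  TM5: {first: 267, last: 297}
  ICL3: {first: 298, last: 336}
  TM6: {first: 337, last: 367}
  ECL3: {first: 368, last: 376}
  TM7: {first: 377, last: 401}
  H8: {first: 402, last: 412}
pivots:
  TM6: 358
  TM7: 394
bw_anchors:
  "1.50": 134
  "2.50": 163
  "3.50": 214
  "4.50": 241   # approximate
  "5.50": 286
  "6.50": 358
  "7.50": 394
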