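# Default structural-region spans in AMPKalpha2 author numbering.
# Spans must be pairwise disjoint; each value is a list of inclusive
# [start, end] residue ranges.  Boundaries are approximate and editable:
# they delimit the N-lobe, a ring around the ATP pocket (hinge plus
# catalytic loop), the activation loop, and the C-lobe helices of the
# kinase domain (residues 6-280).
N-lobe:
  - [6, 93]
ATP-pocket:
  - [94, 100]
  - [140, 150]
activation-loop:
  - [157, 182]
C-lobe-helices:
  - [101, 139]
  - [151, 156]
  - [183, 280]
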