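# Backbone dihedral cluster library for the x-DFG-x window.
# Each cluster gives centroid Phi/Psi angles (degrees) for the five
# residues (x-DFG, DFG-Asp, DFG-Phe, DFG-Gly, DFG+2); null means the
# cluster does not constrain that angle and it is excluded from the mean
# circular distance.  Centroids are APPROXIMATE curated stand-ins
# transcribed from the published kinase structural-state nomenclature
# (cluster names follow that scheme); edit or replace this file to use
# exact centroids.  A structure is "unassigned" when its mean per-angle
# circular distance to every centroid exceeds assignment_cutoff.
assignment_cutoff: 45.0
clusters:
  BLAminus:
    phi: [-129.0, 61.0, -97.0, null, null]
    psi: [179.0, 81.0, 20.0, null, null]
  BLAplus:
    phi: [-119.0, 59.0, -89.0, null, null]
    psi: [168.0, 34.0, -8.0, null, null]
  ABAminus:
    phi: [-112.0, -141.0, -128.0, null, null]
    psi: [-8.0, 148.0, 23.0, null, null]
  BLBminus:
    phi: [-135.0, 60.0, -79.0, null, null]
    psi: [175.0, 65.0, 145.0, null, null]
  BLBplus:
    phi: [-125.0, 60.0, -85.0, null, null]
    psi: [172.0, 33.0, 145.0, null, null]
  BLBtrans:
    phi: [-106.0, 69.0, -62.0, null, null]
    psi: [157.0, 21.0, 134.0, null, null]
  BBAminus:
    phi: [-139.0, -108.0, -140.0, null, null]
    psi: [126.0, 23.0, 18.0, null, null]
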