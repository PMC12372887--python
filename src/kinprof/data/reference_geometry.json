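{
  "description": "Curated published conformational measurements for AMPKalpha2 kinase-domain inhibitor co-structures: diagnostic distances (Angstrom; D1 = Leu68 CA - Phe158 CZ, D2 = Lys45 CA - Phe158 CZ, lys_glu = Lys45 CB - Glu64 CB) and x-DFG-x backbone Phi/Psi angles (degrees) for residues Ala156-Leu160. Used as reference inputs for classification and for building synthetic stand-in structures.",
  "structures": {
    "alpha2KD-BAY-3827": {
      "pdb_id": null,
      "d1": 12.4, "d2": 18.4, "lys_glu": 11.7,
      "xdfgx": {
        "156": [-77.8, 133.2],
        "157": [-64.3, 162.0],
        "158": [-90.6, 42.6],
        "159": [-91.5, 174.0],
        "160": [-69.5, -13.6]
      }
    },
    "T172D-compoundC": {
      "pdb_id": "3AQV",
      "d1": 11.4, "d2": 16.6, "lys_glu": 11.3,
      "xdfgx": {
        "156": [-77.6, 137.5],
        "157": [-58.4, 143.4],
        "158": [-127.8, 21.4],
        "159": [-78.7, -145.7],
        "160": [-61.1, -34.9]
      }
    },
    "T172D-SBI0206965": {
      "pdb_id": "6BX6",
      "d1": 13.1, "d2": 18.2, "lys_glu": 11.8,
      "xdfgx": {
        "156": [-83.3, 141.7],
        "157": [-56.9, 150.6],
        "158": [-90.9, 68.7],
        "159": [-125.6, 179.3],
        "160": [-68.2, -25.5]
      }
    }
  }
}
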