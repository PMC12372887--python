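{
  "description": "Robinson-Robinson amino-acid background frequencies (normalized at load time). Override with any mapping of the 20 standard one-letter codes to positive frequencies.",
  "frequencies": {
    "A": 0.0780, "R": 0.0512, "N": 0.0448, "D": 0.0536, "C": 0.0192,
    "Q": 0.0426, "E": 0.0629, "G": 0.0738, "H": 0.0219, "I": 0.0514,
    "L": 0.0901, "K": 0.0574, "M": 0.0224, "F": 0.0386, "P": 0.0520,
    "S": 0.0712, "T": 0.0584, "W": 0.0132, "Y": 0.0321, "V": 0.0644
  }
}
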