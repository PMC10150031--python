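{
  "self-winding": {"A": 99, "J": 99, "O": 99, "V": 99},
  "adhesion": {"B": 99, "D": 99, "F": 99, "H": 66, "K": 96, "M": 99, "P": 90, "T": 99, "W": 99},
  "inter-overlapped": {"C": 99, "E": 99, "G": 41, "I": 80, "L": 99, "N": 67, "Q": 99, "S": 99, "X": 99}
}
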