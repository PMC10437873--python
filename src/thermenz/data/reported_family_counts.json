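{
  "merops_secreted_family_counts_by_catalytic_type": {
    "M": 59,
    "S": 32,
    "C": 29,
    "A": 9,
    "N": 5,
    "T": 4,
    "U": 4,
    "G": 1,
    "P": 1
  },
  "cazy_family_counts_by_class": {
    "GH": 89,
    "CBM": 31,
    "PL": 17,
    "CE": 10,
    "GT": 7,
    "AA": 2
  }
}
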