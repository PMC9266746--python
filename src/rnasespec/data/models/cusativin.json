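{
  "name": "cusativin",
  "description": "Cusativin: cytidine-directed cleavage 3' of C (CpG/CpU 80-100, CpA/UpA 70-90) with moderate ApU/UpU (14-30) and no cleavage when the 3' base is C. Probabilities are midpoints of the published ranges. Overrides: Cp[m22G] 48-62 and [m5C]pU 98-100 observed on modified tRNA substrates.",
  "product_terminus3": "cyclic_phosphate",
  "p": {
    "CpG": 0.90,
    "CpU": 0.90,
    "CpA": 0.80,
    "UpA": 0.80,
    "ApU": 0.22,
    "UpU": 0.22
  },
  "overrides": {
    "Cp[m22G]": 0.55,
    "[m5C]pU": 0.99
  }
}
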