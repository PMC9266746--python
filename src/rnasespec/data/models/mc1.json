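{
  "name": "rnase_mc1",
  "description": "RNase MC1: uridine-directed cleavage 5' of U. Probabilities are midpoints of the published per-dinucleotide efficiency ranges (ApU 70-100, CpU 80-100, UpU 45-60, GpU 1-1.5, CpA 10-20, ApA/ApC/UpA 0-5, CpG 0-1; all other NpN 0). Overrides encode modified-nucleotide behaviour: dihydrouridine acts as U ([D]p[D] 64-68), [m5C]pU 99-100, while m1A/m7G/G at the 5' position block cleavage.",
  "product_terminus3": "cyclic_phosphate",
  "p": {
    "ApU": 0.85,
    "CpU": 0.90,
    "UpU": 0.525,
    "GpU": 0.0125,
    "CpA": 0.15,
    "ApA": 0.025,
    "ApC": 0.025,
    "UpA": 0.025,
    "CpG": 0.005
  },
  "overrides": {
    "[D]p[D]": 0.66,
    "[m5C]pU": 0.995,
    "Gp[D]": 0.0,
    "[m7G]pU": 0.0,
    "[m1A]pU": 0.0
  }
}
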