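{
  "name": "rnase_t1",
  "description": "RNase T1: complete cleavage 3' of every guanosine (GpN), leaving 5'-OH / 2',3'-cyclic phosphate products. Complete-digest idealization.",
  "product_terminus3": "cyclic_phosphate",
  "p": {
    "GpA": 1.0,
    "GpC": 1.0,
    "GpG": 1.0,
    "GpU": 1.0
  },
  "overrides": {}
}
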