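"""Digest the probe in silico with a guanosine-specific and a
uridine-directed cleavage model.

Products follow the independent-cut model: a fragment i..j appears when both
its boundary bonds are cut and every internal bond survives.  Internal
products carry 5'-OH and 2',3'-cyclic phosphate termini, the hallmark of
transesterifying ribonucleases.
"""

from rnasespec import enumerate_products, expected_abundances, load_model, probe31

probe = probe31()

t1 = load_model("t1")  # cuts 3' of every G with probability 1
print("complete guanosine-specific digest:")
for p in enumerate_products(probe, t1):
    print(f"  {p.start:>2}-{p.end:<2}  {p.sequence}  "
          f"(5'-{p.sequence.terminus5}, 3'-{p.sequence.terminus3})")
# 9 fragments tile the parent; every fragment boundary sits 3' of a G.

mc1 = load_model("mc1")  # uridine-directed, Table-style midpoint probabilities
ea = expected_abundances(probe, mc1, n_molecules=10_000)
top = ea.sort_values("expected_count", ascending=False).head(8)
print("\nmost abundant products of a partial uridine-directed digest "
      "(10,000 molecules):")
print(top[["start", "end", "sequence", "n_missed", "expected_count"]]
      .to_string(index=False))
# Expected counts conserve residue mass exactly:
total = (ea["length"] * ea["expected_count"]).sum()
print(f"\nmass conservation: sum(length x count) = {total:.1f} "
      f"= {len(probe)} nt x 10,000 molecules")
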