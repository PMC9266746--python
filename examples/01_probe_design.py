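"""Audit the 31-nt reference probe and design a fresh one.

A specificity probe must contain every ordered dinucleotide NpN (4^2 = 16)
so that a single digest can interrogate every bond class, plus homopolymer
runs so XpX bonds are probed in a run context.
"""

from rnasespec import coverage, design_probe, probe31

probe = probe31()
rep = coverage(probe)
print(f"reference probe  : {probe}")
print(f"length           : {rep.length} nt")
print(f"dinucleotides    : {rep.n_distinct}/16 ordered pairs present")
print(f"homopolymer runs : {[(b, s, n) for b, s, n in rep.homopolymer_runs]}")
print()
# 16/16 means every bond class is probed at least once; the four runs (AAA,
# CCC, GGG, UUU) give each XpX bond a run context.

fresh = design_probe(require_runs={"A": 3, "C": 3, "G": 3, "U": 3},
                     forbidden_motifs=["GGGG"], seed=11)
fresh_rep = coverage(fresh)
print(f"designed probe   : {fresh}")
print(f"length           : {fresh_rep.length} nt "
      f"({fresh_rep.n_distinct}/16 dinucleotides, "
      f"{len(fresh_rep.homopolymer_runs)} runs)")
# The designer linearizes an order-2 de Bruijn cycle (17 nt is the floor for
# 16 ordered pairs) and then grows the required homopolymer runs.
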