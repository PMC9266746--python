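"""Independent oracles used by the test suite.

Everything here is deliberately written without touching the package's own
mass table, digestion enumeration or efficiency code paths:

* masses come from a hand-entered CODATA atomic-mass table and residue
  compositions assembled as nucleobase + ribose-phosphate;
* digestion expectations come from exhaustive enumeration of all 2^(n-1)
  cut patterns of the independent-cut model;
* per-bond efficiencies are recomputed from first principles on the
  enumerated fragment table.
"""

from __future__ import annotations

import itertools
import re
from collections import Counter

# CODATA 2018 monoisotopic atomic masses (Da)
ATOMIC_MASS = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
}

PROTON = 1.007276466879


def formula_mass(formula: str) -> float:
    """Monoisotopic mass of a simple Hill-style formula like C10H14N5O8P."""
    mass = 0.0
    for el, count in re.findall(r"([A-Z][a-z]?)(\d*)", formula):
        if not el:
            continue
        mass += ATOMIC_MASS[el] * (int(count) if count else 1)
    return mass


def combine(*terms: tuple[str, int]) -> Counter:
    """Sum elemental formulas with signed multiplicities into atom counts."""
    total: Counter = Counter()
    for formula, mult in terms:
        for el, count in re.findall(r"([A-Z][a-z]?)(\d*)", formula):
            if el:
                total[el] += mult * (int(count) if count else 1)
    return total


def counter_mass(atoms: Counter) -> float:
    return sum(ATOMIC_MASS[el] * n for el, n in atoms.items())


# Neutral nucleobases (the species released in base loss).
BASE_FORMULA = {
    "A": "C5H5N5",        # adenine
    "C": "C4H5N3O",       # cytosine
    "G": "C5H5N5O",       # guanine
    "U": "C4H4N2O2",      # uracil
    "m5C": "C5H7N3O",
    "m7G": "C6H7N5O",
    "m1A": "C6H7N5",
    "m22G": "C7H9N5O",
    "D": "C4H6N2O2",      # 5,6-dihydrouracil
}

# Internal chain residue = nucleobase - H (glycosidic bond) + ribose phosphate.
RIBOSE_PHOSPHATE = "C5H8O6P"
WATER = "H2O"
HPO3 = "HPO3"


def residue_mass(code: str) -> float:
    atoms = combine((BASE_FORMULA[code], 1), ("H", -1), (RIBOSE_PHOSPHATE, 1))
    return counter_mass(atoms)


def oligo_mass(codes: list[str], terminus5: str = "hydroxyl",
               terminus3: str = "hydroxyl") -> float:
    """Neutral monoisotopic mass of a linear RNA chain with the given termini."""
    mass = sum(residue_mass(c) for c in codes)
    mass += formula_mass(WATER) - formula_mass(HPO3)  # bare 5'-OH/3'-OH chain
    if terminus5 == "phosphate":
        mass += formula_mass(HPO3)
    elif terminus5 != "hydroxyl":
        raise ValueError(terminus5)
    if terminus3 == "phosphate":
        mass += formula_mass(HPO3)
    elif terminus3 == "cyclic_phosphate":
        mass += formula_mass(HPO3) - formula_mass(WATER)
    elif terminus3 != "hydroxyl":
        raise ValueError(terminus3)
    return mass


def brute_force_fragments(n_residues: int, bond_probs: list[float],
                          n_molecules: float = 1.0) -> dict[tuple[int, int], float]:
    """Expected fragment counts by exhaustive enumeration of all cut patterns.

    Each of the 2^(n-1) subsets of bonds is a cut pattern with probability
    prod(p_i if cut else 1-p_i); its fragments are the runs between cuts.
    Returns {(start, end): expected count} with 1-based inclusive bounds.
    """
    assert len(bond_probs) == n_residues - 1
    counts: dict[tuple[int, int], float] = {}
    for pattern in itertools.product((0, 1), repeat=n_residues - 1):
        weight = 1.0
        for cut, p in zip(pattern, bond_probs):
            weight *= p if cut else 1.0 - p
        if weight == 0.0:
            continue
        bounds = [0] + [i + 1 for i, c in enumerate(pattern) if c] + [n_residues]
        for a, b in zip(bounds, bounds[1:]):
            key = (a + 1, b)
            counts[key] = counts.get(key, 0.0) + weight * n_molecules
    return counts


def brute_force_efficiencies(n_residues: int,
                             fragments: dict[tuple[int, int], float]
                             ) -> dict[int, float]:
    """Per-bond 100*x/(x+y) recomputed from a located fragment table.

    x averages the abundance of fragments ending at the bond and starting
    just after it (each cut yields one fragment on each side); y sums
    fragments spanning the bond.  Bonds with x + y = 0 are omitted.
    """
    effs: dict[int, float] = {}
    for bond in range(1, n_residues):
        x = 0.5 * (sum(c for (s, e), c in fragments.items() if e == bond)
                   + sum(c for (s, e), c in fragments.items() if s == bond + 1))
        y = sum(c for (s, e), c in fragments.items() if s <= bond < e)
        if x + y > 0:
            effs[bond] = 100.0 * x / (x + y)
    return effs
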