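"""Cleavage rules and in-silico endonucleolytic digestion.

The generative assumption is the independent-cut model: during a digest each
phosphodiester bond of each molecule is cut independently with a
bond-specific probability determined by the flanking dinucleotide.  A
product spanning residues ``i..j`` then occurs with probability

    P(i, j) = cut(i-1) * cut(j) * prod_{i <= k < j} (1 - cut(k))

with ``cut(0) = cut(n) = 1`` at the molecule ends, i.e. both of its
boundaries are cut and every internal bond is intact.  Expected product
abundances under this model conserve residue mass exactly:
``sum(length * count) == parent_length * n_molecules``.

Cut probabilities live in a :class:`CleavageModel`: a dinucleotide (parent
base pair) probability matrix plus exact-residue-code overrides that take
precedence, which is how modified nucleotides are handled (dihydrouridine
cleaved like U, 5'-m1A or 5'-m7G blocking cleavage, ...).  Directionality
("cleaves 5' of U", "cleaves 3' of C") is always expressed on the ordered
(5' base, 3' base) pair of the scissile bond.

Transesterifying plant RNases leave 5'-OH / 2',3'-cyclic phosphate product
termini; a linear 3'-phosphate mode is available for post-hydrolysis data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (PARENT_BASES, ResidueTable, RnaSequence, default_table,
                   serialize_sequence, tokenize)

__all__ = [
    "CleavageModel",
    "DigestionProduct",
    "bond_probabilities",
    "enumerate_products",
    "expected_abundances",
    "load_model",
    "PRESET_MODELS",
]

PRESET_MODELS = ("t1", "mc1", "cusativin")


def _parse_dinucleotide_key(key: str) -> tuple[str, str]:
    """Parse an ``XpY`` key where X/Y are bare letters or bracketed codes."""
    toks = tokenize(key)
    codes = [c for c, _ in toks]
    if len(codes) != 3 or codes[1] != "p":
        raise ValueError(
            f"bad dinucleotide key {key!r}: expected '<N>p<N>' with bracketed "
            "modification codes, e.g. 'CpU' or '[m1A]pU'")
    return codes[0], codes[2]


@dataclass(frozen=True)
class CleavageModel:
    """Per-dinucleotide cut probabilities with exact-code overrides.

    ``p`` maps ordered parent-base pairs, e.g. ``("C", "U")`` for CpU, to a
    cut probability in [0, 1]; absent pairs are 0.  ``overrides`` maps exact
    residue-code pairs (e.g. ``("m1A", "U")``) and wins over ``p`` when both
    flanking codes match.
    """

    p: dict[tuple[str, str], float] = field(default_factory=dict)
    overrides: dict[tuple[str, str], float] = field(default_factory=dict)
    product_terminus3: str = "cyclic_phosphate"
    name: str = "custom"

    def __post_init__(self):
        for d in (self.p, self.overrides):
            for pair, prob in d.items():
                if not (0.0 <= prob <= 1.0):
                    raise ValueError(f"probability for {pair} out of [0,1]: {prob}")
        for a, b in self.p:
            if a not in PARENT_BASES or b not in PARENT_BASES:
                raise ValueError(f"p keys must be parent-base pairs, got {(a, b)}")
        if self.product_terminus3 not in ("phosphate", "cyclic_phosphate"):
            raise ValueError(f"bad product_terminus3 {self.product_terminus3!r}")

    def validate_codes(self, table: ResidueTable | None = None) -> None:
        table = table or default_table()
        for a, b in self.overrides:
            for code in (a, b):
                if code not in table:
                    raise ValueError(f"override references unknown residue code {code!r}")

    def bond_probability(self, seq: RnaSequence, bond: int,
                         table: ResidueTable | None = None) -> float:
        """Cut probability of bond ``bond`` (1-based) of ``seq``."""
        table = table or default_table()
        c5, c3 = seq.residues[bond - 1], seq.residues[bond]
        if (c5, c3) in self.overrides:
            return self.overrides[(c5, c3)]
        return self.p.get((table[c5].parent_base, table[c3].parent_base), 0.0)

    @classmethod
    def uniform(cls, prob: float, product_terminus3: str = "cyclic_phosphate") -> "CleavageModel":
        """Same cut probability at every bond (nonspecific nuclease)."""
        return cls(p={(a, b): prob for a in PARENT_BASES for b in PARENT_BASES},
                   product_terminus3=product_terminus3, name=f"uniform({prob})")

    @classmethod
    def from_dict(cls, d: dict) -> "CleavageModel":
        p = {_parse_dinucleotide_key(k): float(v) for k, v in d.get("p", {}).items()}
        overrides = {_parse_dinucleotide_key(k): float(v)
                     for k, v in d.get("overrides", {}).items()}
        return cls(p=p, overrides=overrides,
                   product_terminus3=d.get("product_terminus3", "cyclic_phosphate"),
                   name=d.get("name", "custom"))

    def to_dict(self) -> dict:
        def key(pair: tuple[str, str]) -> str:
            a, b = pair
            a = a if a in PARENT_BASES else f"[{a}]"
            b = b if b in PARENT_BASES else f"[{b}]"
            return f"{a}p{b}"

        return {
            "name": self.name,
            "product_terminus3": self.product_terminus3,
            "p": {key(k): v for k, v in sorted(self.p.items())},
            "overrides": {key(k): v for k, v in sorted(self.overrides.items())},
        }

    @classmethod
    def from_json(cls, path: str | Path) -> "CleavageModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")


def load_model(name_or_path: str) -> CleavageModel:
    """Load a preset model by name (``t1``, ``mc1``, ``cusativin``) or a JSON path."""
    if name_or_path in PRESET_MODELS:
        with resources.as_file(
                resources.files("rnasespec.data") / "models" / f"{name_or_path}.json") as p:
            return CleavageModel.from_json(p)
    if name_or_path.startswith("uniform(") and name_or_path.endswith(")"):
        return CleavageModel.uniform(float(name_or_path[8:-1]))
    return CleavageModel.from_json(name_or_path)


@dataclass(frozen=True)
class DigestionProduct:
    """A located digestion fragment of a parent molecule.

    ``start``/``end`` are 1-based inclusive parent positions.  Internal cut
    boundaries carry 5'-OH and the model's 3' terminus; the parent's own
    termini are preserved at positions 1 and n.
    """

    start: int
    end: int
    sequence: RnaSequence
    probability: float
    n_missed: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def bond_probabilities(parent: RnaSequence, model: CleavageModel,
                       table: ResidueTable | None = None) -> np.ndarray:
    """Cut probability of each bond 1..n-1, as an array indexed from 0."""
    return np.array([model.bond_probability(parent, i, table)
                     for i in range(1, len(parent))])


def _product_sequence(parent: RnaSequence, start: int, end: int,
                      product_terminus3: str) -> RnaSequence:
    n = len(parent)
    return parent.subsequence(
        start, end,
        terminus5=parent.terminus5 if start == 1 else "hydroxyl",
        terminus3=parent.terminus3 if end == n else product_terminus3,
    )


def _iter_products(parent: RnaSequence, model: CleavageModel,
                   table: ResidueTable | None):
    """Yield (start, end, probability, n_missed) for every substring with
    nonzero probability under the independent-cut model."""
    n = len(parent)
    p = bond_probabilities(parent, model, table)  # p[k] is bond k+1
    cut = np.concatenate(([1.0], p, [1.0]))  # cut[i] = P(boundary after residue i), cut[0]=cut[n]=1
    for start in range(1, n + 1):
        left = cut[start - 1]
        if left == 0.0:
            continue
        survive = 1.0
        missed = 0
        for end in range(start, n + 1):
            prob = left * survive * cut[end]
            if prob > 0.0:
                yield start, end, prob, missed
            if end < n:
                # bond `end` becomes internal for longer products
                survive *= 1.0 - cut[end]
                if cut[end] > 0.0:
                    missed += 1
                if survive == 0.0:
                    break


def enumerate_products(parent: RnaSequence, model: CleavageModel,
                       max_missed: int = 2, min_probability: float = 1e-4,
                       table: ResidueTable | None = None) -> list[DigestionProduct]:
    """Enumerate digestion products with termini, probabilities and missed cuts.

    ``n_missed`` counts internal bonds with nonzero model probability left
    uncut.  The list is bounded by ``max_missed`` and ``min_probability`` so
    low-probability models stay finite; a complete digest (all probabilities
    0 or 1) yields exactly the substrings delimited by probability-1 bonds.
    Products are ordered by (start, end).
    """
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    out = []
    for start, end, prob, missed in _iter_products(parent, model, table):
        if missed > max_missed or prob < min_probability:
            continue
        out.append(DigestionProduct(
            start=start, end=end,
            sequence=_product_sequence(parent, start, end, model.product_terminus3),
            probability=prob, n_missed=missed))
    return out


def expected_abundances(parent: RnaSequence, model: CleavageModel,
                        n_molecules: float = 1.0,
                        table: ResidueTable | None = None) -> pd.DataFrame:
    """Expected product counts from digesting ``n_molecules`` parent molecules.

    Unlike :func:`enumerate_products` this is exhaustive (no missed-cleavage
    or probability floor), so residue mass is conserved exactly:
    ``sum(length * expected_count) == len(parent) * n_molecules``.

    Returns a DataFrame with one row per product: start, end, length,
    sequence, terminus5, terminus3, n_missed, probability, expected_count.
    """
    rows = []
    for start, end, prob, missed in _iter_products(parent, model, table):
        seq = _product_sequence(parent, start, end, model.product_terminus3)
        rows.append({
            "start": start, "end": end, "length": end - start + 1,
            "sequence": serialize_sequence(seq),
            "terminus5": seq.terminus5, "terminus3": seq.terminus3,
            "n_missed": missed, "probability": prob,
            "expected_count": prob * n_molecules,
        })
    return pd.DataFrame(rows, columns=["start", "end", "length", "sequence", "terminus5",
                                       "terminus3", "n_missed", "probability",
                                       "expected_count"])
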