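"""Residue alphabet, terminus chemistry and neutral masses of RNA oligonucleotides.

An oligonucleotide is modelled as an ordered list of residue codes plus a
terminus chemistry at each end.  A residue is the internal chain unit — a
nucleoside monophosphate minus one water — so a linear chain with 5'-OH and
3'-OH termini has the composition

    sum(residues) + H2O - HPO3

and terminal phosphates (linear or 2',3'-cyclic) are composition deltas on
top of that.  All numeric masses are derived from elemental formulas through
a single atomic-mass table (pyteomics); nothing is transcribed by hand.

Coordinates are 1-based throughout; bond ``i`` is the phosphodiester between
residues ``i`` and ``i+1`` (``1 <= i <= n-1``).

Modified residues are written in brackets (``A[m5C]U``); the bundled residue
table covers the common tRNA modifications (m5C, m7G, m1A, m22G, m2G, D, Y,
m5U) and is user-extensible via TSV.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

from pyteomics.mass import Composition, calculate_mass

__all__ = [
    "PROTON_MASS",
    "WATER_MONO",
    "ResidueDef",
    "ResidueTable",
    "TerminusChem",
    "RnaSequence",
    "default_table",
    "parse_sequence",
    "serialize_sequence",
    "neutral_mass",
    "sequence_composition",
    "read_fasta",
    "write_fasta",
]

PROTON_MASS = 1.007276466879  # mass of H+ in Da (CODATA)

_WATER = Composition(formula="H2O")
_HPO3 = Composition(formula="HPO3")

WATER_MONO = calculate_mass(composition=_WATER)

PARENT_BASES = ("A", "C", "G", "U")


class UnknownResidueError(KeyError):
    """A residue code that does not resolve in the residue table."""

    def __init__(self, code: str, offset: int | None = None):
        self.code = code
        self.offset = offset
        where = f" at offset {offset}" if offset is not None else ""
        super().__init__(f"unknown residue code {code!r}{where}")

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return self.args[0]


@dataclass(frozen=True)
class ResidueDef:
    """One residue code: parent base, elemental formula, derived masses."""

    code: str
    parent_base: str
    formula: str
    base_formula: str
    composition: Composition = field(compare=False)
    base_composition: Composition = field(compare=False)
    monoisotopic_mass: float = field(compare=False)
    average_mass: float = field(compare=False)

    @classmethod
    def from_formulas(cls, code: str, parent_base: str, formula: str,
                      base_formula: str) -> "ResidueDef":
        if parent_base not in PARENT_BASES:
            raise ValueError(
                f"parent_base of {code!r} must be one of {PARENT_BASES}, got {parent_base!r}")
        comp = Composition(formula=formula)
        base = Composition(formula=base_formula)
        return cls(
            code=code,
            parent_base=parent_base,
            formula=formula,
            base_formula=base_formula,
            composition=comp,
            base_composition=base,
            monoisotopic_mass=calculate_mass(composition=comp),
            average_mass=calculate_mass(composition=comp, average=True),
        )


class ResidueTable:
    """Mapping from residue code to :class:`ResidueDef`.

    Loaded from a TSV with columns ``code, parent_base, formula,
    base_formula``; the packaged default covers A/C/G/U and common
    modifications.  ``add`` extends the table at run time.
    """

    def __init__(self, defs: Iterable[ResidueDef]):
        self._defs: dict[str, ResidueDef] = {}
        for d in defs:
            if d.code in self._defs:
                raise ValueError(f"duplicate residue code {d.code!r}")
            self._defs[d.code] = d

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ResidueTable":
        defs = []
        with open(path) as fh:
            header: list[str] | None = None
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if header is None:
                    header = fields
                    expected = ["code", "parent_base", "formula", "base_formula"]
                    if header != expected:
                        raise ValueError(
                            f"{path}: expected columns {expected}, got {header}")
                    continue
                if len(fields) != 4:
                    raise ValueError(f"{path}:{lineno}: expected 4 fields, got {len(fields)}")
                defs.append(ResidueDef.from_formulas(*fields))
        return cls(defs)

    def __getitem__(self, code: str) -> ResidueDef:
        try:
            return self._defs[code]
        except KeyError:
            raise UnknownResidueError(code) from None

    def __contains__(self, code: str) -> bool:
        return code in self._defs

    def __iter__(self) -> Iterator[ResidueDef]:
        return iter(self._defs.values())

    def __len__(self) -> int:
        return len(self._defs)

    def add(self, code: str, parent_base: str, formula: str, base_formula: str) -> ResidueDef:
        d = ResidueDef.from_formulas(code, parent_base, formula, base_formula)
        if code in self._defs:
            raise ValueError(f"residue code {code!r} already defined")
        self._defs[code] = d
        return d


@functools.lru_cache(maxsize=1)
def default_table() -> ResidueTable:
    """The packaged residue table (cached singleton)."""
    with resources.as_file(resources.files("rnasespec.data") / "residues.tsv") as p:
        return ResidueTable.from_tsv(p)


# Terminus chemistry.  Deltas are relative to the bare 5'-OH / 3'-OH chain.
_TERMINUS_DELTAS: dict[tuple[str, str], Composition] = {
    ("hydroxyl", "5prime"): Composition(),
    ("phosphate", "5prime"): Composition(_HPO3),
    ("hydroxyl", "3prime"): Composition(),
    ("phosphate", "3prime"): Composition(_HPO3),
    # transesterification intermediate: one water lighter than a linear phosphate
    ("cyclic_phosphate", "3prime"): Composition(_HPO3) - _WATER,
}

TERMINUS_KINDS_5 = ("hydroxyl", "phosphate")
TERMINUS_KINDS_3 = ("hydroxyl", "phosphate", "cyclic_phosphate")


@dataclass(frozen=True)
class TerminusChem:
    """Terminus chemistry at one end of a chain.

    ``cyclic_phosphate`` (the 2',3'-cyclic ``>p`` left by transesterifying
    endonucleases) is valid only at the 3' end.
    """

    kind: str
    end: str  # "5prime" | "3prime"

    def __post_init__(self):
        if self.end not in ("5prime", "3prime"):
            raise ValueError(f"end must be 5prime or 3prime, got {self.end!r}")
        if (self.kind, self.end) not in _TERMINUS_DELTAS:
            raise ValueError(f"invalid terminus {self.kind!r} at {self.end}")

    @property
    def composition_delta(self) -> Composition:
        return _TERMINUS_DELTAS[(self.kind, self.end)]

    @property
    def mass_delta(self) -> float:
        """Monoisotopic delta (Da) relative to a hydroxyl end."""
        return calculate_mass(composition=self.composition_delta)


@dataclass(frozen=True)
class RnaSequence:
    """An RNA chain: residue codes plus terminus chemistry at each end.

    Residues are stored as codes and resolved against a
    :class:`ResidueTable` when masses are needed, so a sequence is cheap to
    slice and hash.  Default termini are 5'-OH / 3'-OH (synthetic RNA as
    purchased).
    """

    residues: tuple[str, ...]
    terminus5: str = "hydroxyl"
    terminus3: str = "hydroxyl"
    id: str | None = None

    def __post_init__(self):
        if len(self.residues) < 1:
            raise ValueError("an RnaSequence needs at least one residue")
        TerminusChem(self.terminus5, "5prime")
        TerminusChem(self.terminus3, "3prime")

    def __len__(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return serialize_sequence(self)

    def parent_bases(self, table: ResidueTable | None = None) -> tuple[str, ...]:
        table = table or default_table()
        return tuple(table[c].parent_base for c in self.residues)

    def subsequence(self, start: int, end: int, *, terminus5: str | None = None,
                    terminus3: str | None = None, id: str | None = None) -> "RnaSequence":
        """Residues ``start..end`` (1-based, inclusive) as a new sequence."""
        if not (1 <= start <= end <= len(self)):
            raise ValueError(f"invalid subsequence bounds {start}..{end} for length {len(self)}")
        return RnaSequence(
            residues=self.residues[start - 1:end],
            terminus5=terminus5 if terminus5 is not None else self.terminus5,
            terminus3=terminus3 if terminus3 is not None else self.terminus3,
            id=id,
        )

    def with_termini(self, terminus5: str | None = None,
                     terminus3: str | None = None) -> "RnaSequence":
        return replace(self,
                       terminus5=terminus5 if terminus5 is not None else self.terminus5,
                       terminus3=terminus3 if terminus3 is not None else self.terminus3)

    def dinucleotide(self, bond: int, table: ResidueTable | None = None,
                     *, by_code: bool = False) -> str:
        """NpN label of phosphodiester bond ``bond`` (1-based, bond i joins i and i+1)."""
        if not (1 <= bond <= len(self) - 1):
            raise ValueError(f"bond index {bond} out of range 1..{len(self) - 1}")
        if by_code:
            a, b = self.residues[bond - 1], self.residues[bond]
            return f"{_bracket(a)}p{_bracket(b)}"
        bases = self.parent_bases(table)
        return f"{bases[bond - 1]}p{bases[bond]}"


def _bracket(code: str) -> str:
    # every modification code is bracketed, even single-letter ones like D
    return code if code in PARENT_BASES else f"[{code}]"


def tokenize(text: str) -> list[tuple[str, int]]:
    """Split sequence text into (code, offset) pairs; brackets delimit multi-char codes."""
    tokens: list[tuple[str, int]] = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch == "[":
            j = text.find("]", i)
            if j < 0:
                raise ValueError(f"unbalanced '[' at offset {i}")
            if j == i + 1:
                raise ValueError(f"empty brackets at offset {i}")
            tokens.append((text[i + 1:j], i))
            i = j + 1
        elif ch == "]":
            raise ValueError(f"unbalanced ']' at offset {i}")
        elif ch.isspace():
            i += 1
        else:
            tokens.append((ch, i))
            i += 1
    return tokens


def parse_sequence(text: str, *, terminus5: str = "hydroxyl", terminus3: str = "hydroxyl",
                   id: str | None = None, table: ResidueTable | None = None) -> RnaSequence:
    """Parse sequence text with bracketed modification codes into an :class:`RnaSequence`.

    Raises :class:`UnknownResidueError` naming the offending token and its
    character offset, and ``ValueError`` on empty input or unbalanced brackets.
    """
    if not text or not text.strip():
        raise ValueError("empty sequence text")
    table = table or default_table()
    codes = []
    for code, offset in tokenize(text):
        if code not in table:
            raise UnknownResidueError(code, offset)
        codes.append(code)
    return RnaSequence(tuple(codes), terminus5=terminus5, terminus3=terminus3, id=id)


def serialize_sequence(seq: RnaSequence) -> str:
    """Canonical text form: one-letter codes bare, modification codes bracketed."""
    return "".join(_bracket(c) for c in seq.residues)


def sequence_composition(seq: RnaSequence, table: ResidueTable | None = None) -> Composition:
    """Elemental composition of the neutral molecule, termini included."""
    table = table or default_table()
    comp = Composition()
    for code in seq.residues:
        comp += table[code].composition
    comp += _WATER
    comp -= _HPO3
    comp += TerminusChem(seq.terminus5, "5prime").composition_delta
    comp += TerminusChem(seq.terminus3, "3prime").composition_delta
    return comp


def neutral_mass(seq: RnaSequence, kind: str = "monoisotopic",
                 table: ResidueTable | None = None) -> float:
    """Neutral mass in Da; ``kind`` is ``monoisotopic`` or ``average``.

    Depends only on the residue multiset and the termini (composition
    additivity), so sequence isomers are isobaric.
    """
    if kind not in ("monoisotopic", "average"):
        raise ValueError(f"kind must be monoisotopic or average, got {kind!r}")
    comp = sequence_composition(seq, table)
    return calculate_mass(composition=comp, average=(kind == "average"))


def read_fasta(path: str | Path, *, terminus5: str = "hydroxyl", terminus3: str = "hydroxyl",
               table: ResidueTable | None = None) -> list[RnaSequence]:
    """Read FASTA whose sequence lines may contain bracketed modification codes."""
    from Bio import SeqIO

    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(parse_sequence(str(rec.seq), terminus5=terminus5,
                                      terminus3=terminus3, id=rec.id, table=table))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(seqs: Iterable[RnaSequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, seq in enumerate(seqs):
            fh.write(f">{seq.id or f'seq{i + 1}'}\n{serialize_sequence(seq)}\n")


def probe31() -> RnaSequence:
    """The packaged 31-nt reference specificity probe (5'-OH/3'-OH)."""
    with resources.as_file(resources.files("rnasespec.data") / "probe31.fasta") as p:
        return read_fasta(p)[0]
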