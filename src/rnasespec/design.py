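"""Design and validate probe RNAs that cover all 16 dinucleotide combinations.

A single substrate containing every ordered NpN pair (4^2 = 16) plus
homopolymer runs lets one assay read out an endonuclease's dinucleotide
preference at every bond class.  ``coverage`` audits an existing sequence;
``design_probe`` builds one from a linearized order-2 de Bruijn cycle over
{A,C,G,U} (16 edges -> 17 nt, the information-theoretic floor) and then
extends homopolymer runs greedily to meet per-base run constraints.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import networkx as nx

from .core import PARENT_BASES, ResidueTable, RnaSequence, parse_sequence

__all__ = ["CoverageReport", "coverage", "design_probe", "ALL_DINUCLEOTIDES"]

ALL_DINUCLEOTIDES = frozenset(
    (a, b) for a in PARENT_BASES for b in PARENT_BASES)

#: a "homopolymer run" is >= 3 identical bases; length-2 repeats are already
#: counted as their XpX dinucleotide
MIN_RUN_LENGTH = 3


@dataclass(frozen=True)
class CoverageReport:
    """Dinucleotide and homopolymer audit of a probe sequence."""

    dinucleotides_present: frozenset[tuple[str, str]]
    homopolymer_runs: tuple[tuple[str, int, int], ...]  # (base, 1-based start, length)
    length: int

    @property
    def n_distinct(self) -> int:
        return len(self.dinucleotides_present)

    @property
    def missing(self) -> frozenset[tuple[str, str]]:
        return ALL_DINUCLEOTIDES - self.dinucleotides_present

    @property
    def complete(self) -> bool:
        return self.n_distinct == 16

    def to_dict(self) -> dict:
        return {
            "length": self.length,
            "n_distinct_dinucleotides": self.n_distinct,
            "dinucleotides_present": sorted(f"{a}p{b}" for a, b in self.dinucleotides_present),
            "dinucleotides_missing": sorted(f"{a}p{b}" for a, b in self.missing),
            "homopolymer_runs": [
                {"base": b, "start": s, "length": n} for b, s, n in self.homopolymer_runs],
        }


def coverage(seq: RnaSequence, table: ResidueTable | None = None) -> CoverageReport:
    """Report the ordered dinucleotides present and all maximal runs of >= 3.

    Modified residues are classified by their parent base.
    """
    bases = seq.parent_bases(table)
    pairs = frozenset(zip(bases, bases[1:]))
    runs: list[tuple[str, int, int]] = []
    i = 0
    while i < len(bases):
        j = i
        while j < len(bases) and bases[j] == bases[i]:
            j += 1
        if j - i >= MIN_RUN_LENGTH:
            runs.append((bases[i], i + 1, j - i))
        i = j
    return CoverageReport(pairs, tuple(runs), len(bases))


def _de_bruijn_linear(rng: random.Random) -> str:
    """A linearized order-2 de Bruijn sequence over {A,C,G,U}: 17 nt, all 16 pairs.

    Eulerian circuit on the complete 4-node multigraph with one edge per
    ordered pair (self-loops included); edge order is shuffled by ``rng`` so
    different seeds yield different probes.
    """
    g = nx.MultiDiGraph()
    edges = [(a, b) for a in PARENT_BASES for b in PARENT_BASES]
    rng.shuffle(edges)
    g.add_edges_from(edges)
    start = rng.choice(PARENT_BASES)
    circuit = list(nx.eulerian_circuit(g, source=start))
    return circuit[0][0] + "".join(v for _, v in circuit)


def _insert_runs(seq: str, require_runs: dict[str, int], rng: random.Random) -> str:
    """Extend an existing occurrence of each base to the required run length."""
    for base in sorted(require_runs):
        need = require_runs[base]
        if need < 1:
            continue
        # longest existing run of this base
        best_start, best_len = -1, 0
        i = 0
        while i < len(seq):
            j = i
            while j < len(seq) and seq[j] == base:
                j += 1
            if seq[i:j] and j - i > best_len:
                best_start, best_len = i, j - i
            i = j + 1 if j == i else j
        if best_len >= need:
            continue
        if best_start < 0:  # base absent (cannot happen after de Bruijn step)
            pos = rng.randrange(len(seq) + 1)
            seq = seq[:pos] + base * need + seq[pos:]
        else:
            seq = seq[:best_start] + base * need + seq[best_start + best_len:]
    return seq


def design_probe(require_runs: dict[str, int] | None = None,
                 forbidden_motifs: list[str] | None = None,
                 seed: int = 0,
                 max_attempts: int = 200,
                 table: ResidueTable | None = None) -> RnaSequence:
    """Design a probe covering all 16 dinucleotides, deterministically per seed.

    Parameters
    ----------
    require_runs
        Per-base minimum homopolymer run length, e.g. ``{"A": 3, "U": 3}``.
    forbidden_motifs
        Motifs (plain base strings) the result must not contain.
    seed
        Seeds the randomized de Bruijn edge order; a fixed seed gives a fixed
        probe.

    Raises ``ValueError`` if the constraints cannot be satisfied within
    ``max_attempts`` randomized restarts (e.g. contradictory run/motif
    constraints such as a required AAA run with AAA forbidden).
    """
    require_runs = dict(require_runs or {})
    forbidden = list(forbidden_motifs or [])
    for base in require_runs:
        if base not in PARENT_BASES:
            raise ValueError(f"run constraint on unknown base {base!r}")
    for motif in forbidden:
        for base, need in require_runs.items():
            if motif in base * need:
                raise ValueError(
                    f"unsatisfiable: required {base}-run of {need} contains forbidden motif {motif!r}")
    rng = random.Random(seed)
    for _ in range(max_attempts):
        cand = _de_bruijn_linear(rng)
        cand = _insert_runs(cand, require_runs, rng)
        rep = coverage(parse_sequence(cand, table=table), table=table)
        if not rep.complete:
            continue
        if any(m in cand for m in forbidden):
            continue
        ok = True
        for base, need in require_runs.items():
            if not any(b == base and n >= need for b, _, n in rep.homopolymer_runs):
                ok = False
        if ok:
            return parse_sequence(cand, id=f"probe_seed{seed}", table=table)
    raise ValueError(
        f"could not satisfy probe constraints within {max_attempts} attempts "
        f"(runs={require_runs}, forbidden={forbidden})")
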