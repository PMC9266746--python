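"""m/z arithmetic, CID fragment ladders and tolerance-based peak matching.

Oligonucleotides ionize in negative mode, so observed species are
deprotonated: ``m/z = (M - |z| * m_H+) / |z|`` for charge ``z <= -1``.

Fragment nomenclature follows the standard nucleic-acid scheme: cleavage of
the four backbone bonds between two residues gives 5'-side series a/b/c/d
and 3'-side series w/x/y/z.  Neutral fragment masses are built from
subsequence compositions:

    b_i = residues 1..i, parent 5' terminus, 3'-OH          a_i = b_i - H2O
    c_i = residues 1..i, parent 5' terminus, 3'-phosphate   d_i = c_i + H2O
    y_j = last j residues, 5'-OH, parent 3' terminus        z_j = y_j - H2O
    w_j = y_j + HPO3 (5'-phosphate)                         x_j = w_j - H2O

so complementary pairs satisfy c_i + y_{n-i} = M + H2O for every i.  a-B
ions additionally lose the 3'-terminal nucleobase of the a fragment.  The
default ladder is the dominant RNA CID channels c / y / w / a-B; the full
eight series are available on request.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import (PROTON_MASS, WATER_MONO, ResidueTable, RnaSequence,
                   default_table, calculate_mass, neutral_mass, serialize_sequence)
from .digest import DigestionProduct

__all__ = ["FragmentIon", "PeakMatch", "mz", "fragment_ladder", "match_products",
           "theoretical_peaks", "DEFAULT_SERIES", "ALL_SERIES"]

DEFAULT_SERIES = ("c", "y", "w", "a-B")
ALL_SERIES = ("a", "a-B", "b", "c", "d", "w", "x", "y", "z")

_HPO3_MONO = calculate_mass(formula="HPO3")


def mz(neutral_mass: float, charge: int) -> float:
    """m/z of a deprotonated anion: ``(M - |z| m_H+) / |z|`` for charge <= -1."""
    if charge >= 0:
        raise ValueError(f"charge must be a negative integer, got {charge}")
    z = -charge
    return (neutral_mass - z * PROTON_MASS) / z


@dataclass(frozen=True)
class FragmentIon:
    """One neutral fragment of a ladder series.

    ``index`` counts cleavage positions from the series' reference end (5'
    for a/b/c/d, 3' for w/x/y/z); ``description`` lists the residues covered
    and ``lost_base`` is set for a-B ions.
    """

    series: str
    index: int
    neutral_mass: float
    description: str
    lost_base: str | None = None


def fragment_ladder(product: RnaSequence, series: Sequence[str] = DEFAULT_SERIES,
                    table: ResidueTable | None = None) -> list[FragmentIon]:
    """Neutral-mass fragment ladder of ``product`` for the requested series.

    Returns ``n - 1`` ions per series (one per cleavable backbone position);
    a length-1 input has no backbone and yields an empty ladder.
    """
    for s in series:
        if s not in ALL_SERIES:
            raise ValueError(f"unknown fragment series {s!r}; choose from {ALL_SERIES}")
    table = table or default_table()
    n = len(product)
    if n < 2:
        return []
    ions: list[FragmentIon] = []
    five_prime = [s for s in series if s in ("a", "a-B", "b", "c", "d")]
    three_prime = [s for s in series if s in ("w", "x", "y", "z")]
    for i in range(1, n):
        if five_prime:
            sub = product.subsequence(1, i, terminus3="hydroxyl")
            b_mass = neutral_mass(sub, table=table)
            desc = serialize_sequence(sub)
            for s in five_prime:
                if s == "a":
                    m = b_mass - WATER_MONO
                elif s == "a-B":
                    base = table[product.residues[i - 1]]
                    m = (b_mass - WATER_MONO
                         - calculate_mass(composition=base.base_composition))
                elif s == "b":
                    m = b_mass
                elif s == "c":
                    m = b_mass + _HPO3_MONO
                else:  # d
                    m = b_mass + _HPO3_MONO + WATER_MONO
                ions.append(FragmentIon(
                    series=s, index=i, neutral_mass=m, description=desc,
                    lost_base=base.code if s == "a-B" else None))
        if three_prime:
            sub = product.subsequence(n - i + 1, n, terminus5="hydroxyl")
            y_mass = neutral_mass(sub, table=table)
            desc = serialize_sequence(sub)
            for s in three_prime:
                if s == "y":
                    m = y_mass
                elif s == "z":
                    m = y_mass - WATER_MONO
                elif s == "w":
                    m = y_mass + _HPO3_MONO
                else:  # x
                    m = y_mass + _HPO3_MONO - WATER_MONO
                ions.append(FragmentIon(series=s, index=i, neutral_mass=m, description=desc))
    return ions


@dataclass(frozen=True)
class PeakMatch:
    """Assignment of one deconvoluted peak to a candidate product."""

    product_id: str
    start: int
    end: int
    observed_mz: float
    charge: int
    ppm_error: float
    intensity: float
    ambiguous: bool = False


def _candidate_frame(candidates: Iterable[DigestionProduct],
                     table: ResidueTable | None) -> pd.DataFrame:
    rows = []
    for prod in candidates:
        rows.append({
            "product_id": f"{serialize_sequence(prod.sequence)}@{prod.start}-{prod.end}",
            "start": prod.start, "end": prod.end,
            "neutral_mass": neutral_mass(prod.sequence, table=table),
        })
    return pd.DataFrame(rows)


def theoretical_peaks(candidates: Iterable[DigestionProduct],
                      charges: Sequence[int] = (-1, -2, -3),
                      table: ResidueTable | None = None) -> pd.DataFrame:
    """Theoretical (m/z, charge) table for a candidate product list."""
    cand = _candidate_frame(candidates, table)
    rows = []
    for _, row in cand.iterrows():
        for z in charges:
            rows.append({"product_id": row.product_id, "start": row.start,
                         "end": row.end, "charge": z,
                         "mz": mz(row.neutral_mass, z)})
    return pd.DataFrame(rows)


def match_products(candidates: Iterable[DigestionProduct], peaks: pd.DataFrame,
                   tol_ppm: float = 10.0, charges: Sequence[int] = (-1, -2, -3, -4, -5, -6),
                   table: ResidueTable | None = None) -> tuple[list[PeakMatch], pd.DataFrame]:
    """Match candidate products against a deconvoluted peak list.

    ``peaks`` needs columns ``mz`` and ``intensity``; an optional ``charge``
    column (negative integers) restricts each peak to its deconvoluted
    charge, otherwise every charge in ``charges`` is tried.  Each peak is
    assigned to at most one candidate per charge: smallest ``|ppm|`` wins,
    then larger charge magnitude.  Candidates of identical composition
    (sequence isomers) are isobaric and are all reported, flagged
    ``ambiguous``.  Returns ``(matches, unmatched_peaks)``.
    """
    if "mz" not in peaks.columns:
        raise ValueError("peak list must have an 'mz' column")
    peaks = peaks.copy()
    if "intensity" not in peaks.columns:
        peaks["intensity"] = np.nan
    cand = _candidate_frame(candidates, table)
    matches: list[PeakMatch] = []
    unmatched_rows = []
    for _, peak in peaks.iterrows():
        peak_charges = ([int(peak["charge"])] if "charge" in peaks.columns
                        and not pd.isna(peak.get("charge")) else list(charges))
        best: list[tuple[float, int, pd.Series]] = []  # (|ppm|, charge, candidate row)
        for z in peak_charges:
            theo = (cand.neutral_mass - (-z) * PROTON_MASS) / (-z)
            ppm = (peak["mz"] - theo) / theo * 1e6
            ok = np.abs(ppm) <= tol_ppm
            for idx in np.flatnonzero(ok.to_numpy()):
                best.append((float(ppm.iloc[idx]), z, cand.iloc[idx]))
        if not best:
            unmatched_rows.append(peak)
            continue
        best.sort(key=lambda t: (abs(t[0]), t[1]))  # smallest |ppm|, then more-negative z
        top_ppm, top_z, _ = best[0]
        winners = [t for t in best
                   if t[1] == top_z and abs(abs(t[0]) - abs(top_ppm)) < 1e-9]
        ambiguous = len(winners) > 1
        for ppm_err, z, row in winners:
            matches.append(PeakMatch(
                product_id=row.product_id, start=int(row.start), end=int(row.end),
                observed_mz=float(peak["mz"]), charge=z, ppm_error=ppm_err,
                intensity=float(peak["intensity"]), ambiguous=ambiguous))
    unmatched = pd.DataFrame(unmatched_rows).reset_index(drop=True)
    return matches, unmatched
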