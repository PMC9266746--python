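"""Map identified digestion products onto the parent and score per-bond
cleavage efficiency.

Every observed endonucleolytic product testifies to two cuts — one at each
internal boundary — while a product spanning a bond without a cut testifies
to that bond surviving.  For bond ``i`` (between residues ``i`` and
``i+1``):

    x_i = 1/2 * ( sum abundance of products ending at i
                + sum abundance of products starting at i+1 )
    y_i = sum abundance of products spanning i (start <= i < end)
    efficiency_i = 100 * x_i / (x_i + y_i)

The two-end average in ``x`` reflects that each cut releases exactly one
product on each side; under the independent-cut model it makes the
estimator exactly unbiased (efficiency == 100 p) on noiseless expected
abundances with full detection, and halves the bias when one side is below
the detection floor (the undetectable-mononucleotide case).  Molecule
termini are not cut evidence: a product touching position 1 or n
contributes only its internal boundary.

Bonds with x + y = 0 have no coverage and are reported as undefined — never
as 0%.  Efficiencies are categorized on the conventional four-level scale:
< 5 extremely low, 5-25 low, 25-50 moderate, > 50 efficient (boundary
values 5 and 25 belong to the higher band's printed lower edge; exactly 50
is moderate).

Bonds aggregate per exact-code dinucleotide, so e.g. ``[m5C]pU`` is
reported separately from ``CpU`` while both classify as CpU by parent base.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ResidueTable, RnaSequence, default_table, parse_sequence

__all__ = [
    "CATEGORY_LABELS",
    "categorize",
    "read_identifications",
    "place_products",
    "bond_efficiencies",
    "aggregate",
    "EfficiencyProfile",
]

CATEGORY_LABELS = ("extremely_low", "low", "moderate", "efficient")

ID_COLUMNS = ["sequence", "terminus5", "terminus3", "abundance", "replicate"]


def categorize(efficiency: float) -> str | None:
    """Four-level category of a percent efficiency; None for undefined (NaN)."""
    if efficiency is None or (isinstance(efficiency, float) and math.isnan(efficiency)):
        return None
    if not (0.0 <= efficiency <= 100.0):
        raise ValueError(f"efficiency out of [0, 100]: {efficiency}")
    if efficiency < 5.0:
        return "extremely_low"
    if efficiency < 25.0:
        return "low"
    if efficiency <= 50.0:
        return "moderate"
    return "efficient"


def read_identifications(path: str | Path) -> pd.DataFrame:
    """Read an identification table (CSV/TSV) with row-level validation.

    Required columns: sequence, terminus5, terminus3, abundance, replicate;
    optional: start (1-based anchor).  Raises ``ValueError`` naming the
    offending row on negative abundance or missing fields.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    ids = pd.read_csv(path, sep=sep)
    missing = [c for c in ID_COLUMNS if c not in ids.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    bad = ids.index[pd.to_numeric(ids["abundance"], errors="coerce").isna()
                    | (pd.to_numeric(ids["abundance"], errors="coerce") < 0)]
    if len(bad):
        # +2: one for the header line, one for 1-based numbering
        raise ValueError(
            f"{path}: invalid abundance at row {bad[0] + 2} "
            f"(value {ids.loc[bad[0], 'abundance']!r}); abundances must be >= 0")
    ids["abundance"] = ids["abundance"].astype(float)
    return ids


def _find_occurrences(parent_codes: tuple[str, ...], product_codes: tuple[str, ...]) -> list[int]:
    """All 1-based start positions where product occurs as an exact-code substring."""
    n, m = len(parent_codes), len(product_codes)
    return [i + 1 for i in range(n - m + 1) if parent_codes[i:i + m] == product_codes]


def place_products(parent: RnaSequence, ids: pd.DataFrame, mode: str = "split",
                   table: ResidueTable | None = None
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Locate identified products on the parent sequence.

    Anchored rows (a ``start`` column with a value) are placed there after
    checking the anchored substring matches.  Unanchored products are placed
    at every exact occurrence; with ``mode="split"`` the abundance is divided
    equally among placements, with ``mode="unique_only"`` multi-placement
    products are excluded from scoring and reported.  Products that are not
    substrings of the parent are reported as unmapped, not fatal.

    Returns ``(placements, unmapped)``; placements has columns start, end,
    abundance, replicate, sequence, n_placements.
    """
    if mode not in ("split", "unique_only"):
        raise ValueError(f"mode must be 'split' or 'unique_only', got {mode!r}")
    table = table or default_table()
    placements = []
    unmapped = []
    has_anchor = "start" in ids.columns
    for row in ids.itertuples(index=False):
        codes = parse_sequence(str(row.sequence), table=table).residues
        m = len(codes)
        anchor = getattr(row, "start", None) if has_anchor else None
        if anchor is not None and not pd.isna(anchor):
            s = int(anchor)
            if parent.residues[s - 1:s - 1 + m] != codes:
                unmapped.append({**row._asdict(), "reason": f"anchor {s} does not match parent"})
                continue
            occ = [s]
        else:
            occ = _find_occurrences(parent.residues, codes)
        if not occ:
            unmapped.append({**row._asdict(), "reason": "not a substring of parent"})
            continue
        if len(occ) > 1 and mode == "unique_only":
            unmapped.append({**row._asdict(),
                             "reason": f"ambiguous placement at {occ} (unique_only mode)"})
            continue
        share = float(row.abundance) / len(occ)
        for s in occ:
            placements.append({
                "start": s, "end": s + m - 1, "abundance": share,
                "replicate": row.replicate, "sequence": str(row.sequence),
                "n_placements": len(occ),
            })
    cols = ["start", "end", "abundance", "replicate", "sequence", "n_placements"]
    placed = pd.DataFrame(placements, columns=cols)
    return placed, pd.DataFrame(unmapped)


def bond_efficiencies(parent: RnaSequence, placements: pd.DataFrame,
                      replicate=None, table: ResidueTable | None = None) -> pd.DataFrame:
    """Per-bond x, y, efficiency and category for one replicate.

    ``placements`` is the output of :func:`place_products` (optionally
    filtered); if ``replicate`` is given, rows are filtered to it.  Returns
    one row per bond 1..n-1 with columns bond, npn (parent-base class),
    codes (exact-code class), x, y, efficiency (NaN when uncovered),
    category (None when uncovered).
    """
    table = table or default_table()
    n = len(parent)
    if replicate is not None:
        placements = placements[placements["replicate"] == replicate]
    starts = placements.groupby("start")["abundance"].sum() if len(placements) else pd.Series(dtype=float)
    ends = placements.groupby("end")["abundance"].sum() if len(placements) else pd.Series(dtype=float)
    rows = []
    for i in range(1, n):
        # ends at i (i < n so this is a cut boundary) + starts at i+1 (> 1 likewise)
        x = 0.5 * (float(ends.get(i, 0.0)) + float(starts.get(i + 1, 0.0)))
        if len(placements):
            spanning = placements[(placements["start"] <= i) & (placements["end"] > i)]
            y = float(spanning["abundance"].sum())
        else:
            y = 0.0
        # clamp float round-off when y == 0 and x sums many terms
        eff = min(100.0 * x / (x + y), 100.0) if x + y > 0 else float("nan")
        rows.append({
            "bond": i,
            "npn": parent.dinucleotide(i, table),
            "codes": parent.dinucleotide(i, table, by_code=True),
            "x": x, "y": y,
            "efficiency": eff,
            "category": categorize(eff),
        })
    out = pd.DataFrame(rows)
    if replicate is not None:
        out.insert(0, "replicate", replicate)
    return out


@dataclass(frozen=True)
class EfficiencyProfile:
    """Per-bond and per-dinucleotide cleavage-efficiency summary.

    ``per_bond``: one row per bond with mean/sd/min/max efficiency across
    replicates.  ``per_npn``: one row per exact-code dinucleotide class with
    statistics pooled over both replicates and bonds of the class, plus the
    across-bond range of per-bond means (``bond_min``/``bond_max``) since a
    class may be probed at several bonds.
    """

    per_bond: pd.DataFrame
    per_npn: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "per_bond": self.per_bond.to_dict(orient="records"),
            "per_npn": self.per_npn.to_dict(orient="records"),
        }


def _nan_stats(vals: np.ndarray) -> dict:
    vals = vals[~np.isnan(vals)]
    if len(vals) == 0:
        return {"mean": float("nan"), "sd": float("nan"),
                "min": float("nan"), "max": float("nan"), "n_obs": 0}
    return {
        "mean": float(np.mean(vals)),
        "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan"),
        "min": float(np.min(vals)),
        "max": float(np.max(vals)),
        "n_obs": int(len(vals)),
    }


def aggregate(bond_tables: pd.DataFrame | list[pd.DataFrame]) -> EfficiencyProfile:
    """Aggregate per-replicate bond tables into an :class:`EfficiencyProfile`.

    Accepts the concatenation (or a list) of :func:`bond_efficiencies`
    outputs carrying a ``replicate`` column.  A single replicate yields
    sd = NaN and a point range.
    """
    if isinstance(bond_tables, list):
        tab = pd.concat(bond_tables, ignore_index=True)
    else:
        tab = bond_tables.copy()
    if "replicate" not in tab.columns:
        tab.insert(0, "replicate", 1)
    per_bond_rows = []
    for (bond, npn, codes), grp in tab.groupby(["bond", "npn", "codes"], sort=True):
        st = _nan_stats(grp["efficiency"].to_numpy(dtype=float))
        per_bond_rows.append({"bond": bond, "npn": npn, "codes": codes,
                              **st, "n_replicates": int(grp["replicate"].nunique()),
                              "category": categorize(st["mean"])})
    per_bond = pd.DataFrame(per_bond_rows).sort_values("bond").reset_index(drop=True)
    per_npn_rows = []
    for (npn, codes), grp in tab.groupby(["npn", "codes"], sort=True):
        st = _nan_stats(grp["efficiency"].to_numpy(dtype=float))
        bonds = per_bond[per_bond["codes"] == codes]
        per_npn_rows.append({
            "npn": npn, "codes": codes, "n_bonds": int(grp["bond"].nunique()), **st,
            "bond_min": float(bonds["mean"].min()),
            "bond_max": float(bonds["mean"].max()),
            "category": categorize(st["mean"]),
        })
    per_npn = pd.DataFrame(per_npn_rows).sort_values(["npn", "codes"]).reset_index(drop=True)
    return EfficiencyProfile(per_bond=per_bond, per_npn=per_npn)


def profile_identifications(parent: RnaSequence, ids: pd.DataFrame, mode: str = "split",
                            table: ResidueTable | None = None) -> tuple[EfficiencyProfile, pd.DataFrame]:
    """End-to-end convenience: place products, score every replicate, aggregate.

    Returns ``(profile, unmapped)``.
    """
    placed, unmapped = place_products(parent, ids, mode=mode, table=table)
    reps = sorted(placed["replicate"].unique()) if len(placed) else []
    tables = [bond_efficiencies(parent, placed, replicate=r, table=table) for r in reps]
    if not tables:
        tables = [bond_efficiencies(parent, placed, table=table)]
    return aggregate(tables), unmapped
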