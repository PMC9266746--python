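"""Synthetic partial-digest data with known ground truth.

The simulator stands in for the wet steps of a specificity assay — the
enzymatic digest and the LC-MS identification/quantification — so the
profiling pipeline can be exercised end-to-end against a known cleavage
model.  It emulates three features of real identification tables:

* per-bond cut probabilities (the ground-truth :class:`CleavageModel`),
  through the independent-cut expected abundances;
* replicate-level multiplicative noise — each product's abundance in each
  replicate is the expected count times a lognormal(0, sigma) factor, the
  simplest defensible model for positive, roughly proportional peak areas;
* a detection floor hiding short products: mononucleotides (length below
  ``min_detectable_length``, default 2) never reach the table, mirroring
  how single nucleotide monophosphates escape LC-MS detection.

It does not model ionization-efficiency differences between
oligonucleotides, retention times, isotope envelopes or spectral noise.
Identical configurations (including the seed) produce byte-identical
outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import ResidueTable, RnaSequence, neutral_mass, parse_sequence, serialize_sequence
from .digest import CleavageModel, bond_probabilities, expected_abundances
from .spectra import mz

__all__ = ["SimulationConfig", "SimulatedDigest", "simulate_digest",
           "simulate_peaks", "write_simulation"]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated digestion experiment.

    Defaults mirror a typical specificity assay on the 31-nt probe: 4
    independent replicates, moderate (sigma = 0.2) lognormal abundance
    noise, and a 2-nt detection floor.  ``n_molecules`` only sets the
    abundance scale — the efficiency statistic is scale invariant.
    """

    parent: RnaSequence
    model: CleavageModel
    n_molecules: float = 10_000.0
    noise_sigma: float = 0.2
    n_replicates: int = 4
    min_detectable_length: int = 2
    seed: int = 0
    anchored: bool = True  # emit the true start position with each product

    def __post_init__(self):
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.min_detectable_length < 1:
            raise ValueError("min_detectable_length must be >= 1")


@dataclass(frozen=True)
class SimulatedDigest:
    """Simulated identification tables plus the ground truth that made them."""

    ids: pd.DataFrame          # sequence, terminus5, terminus3, abundance, replicate[, start, end]
    truth: pd.DataFrame        # bond, npn, codes, p
    config: SimulationConfig


def ground_truth(parent: RnaSequence, model: CleavageModel,
                 table: ResidueTable | None = None) -> pd.DataFrame:
    """Per-bond true cut probabilities as a table (bond, npn, codes, p)."""
    p = bond_probabilities(parent, model, table)
    return pd.DataFrame({
        "bond": np.arange(1, len(parent)),
        "npn": [parent.dinucleotide(i, table) for i in range(1, len(parent))],
        "codes": [parent.dinucleotide(i, table, by_code=True) for i in range(1, len(parent))],
        "p": p,
    })


def simulate_digest(config: SimulationConfig,
                    table: ResidueTable | None = None) -> SimulatedDigest:
    """Generate replicate identification tables under a known cleavage model.

    Abundance of each detectable product in each replicate is its expected
    count under the independent-cut model times an independent
    lognormal(0, noise_sigma) factor; products shorter than
    ``min_detectable_length`` are dropped.  With ``noise_sigma = 0`` and a
    1-nt floor the tables equal the noiseless expectations exactly.
    """
    rng = np.random.default_rng(config.seed)
    expected = expected_abundances(config.parent, config.model,
                                   config.n_molecules, table)
    detectable = expected[(expected["length"] >= config.min_detectable_length)
                          & (expected["expected_count"] > 0)].reset_index(drop=True)
    frames = []
    for rep in range(1, config.n_replicates + 1):
        noise = (rng.lognormal(mean=0.0, sigma=config.noise_sigma, size=len(detectable))
                 if config.noise_sigma > 0 else np.ones(len(detectable)))
        f = detectable[["sequence", "terminus5", "terminus3"]].copy()
        f["abundance"] = detectable["expected_count"].to_numpy() * noise
        f["replicate"] = rep
        if config.anchored:
            f["start"] = detectable["start"].to_numpy()
            f["end"] = detectable["end"].to_numpy()
        frames.append(f)
    ids = pd.concat(frames, ignore_index=True)
    return SimulatedDigest(ids=ids, truth=ground_truth(config.parent, config.model, table),
                           config=config)


def simulate_peaks(products: pd.DataFrame, charges: Sequence[int] = (-1, -2, -3),
                   ppm_jitter: float = 2.0, seed: int = 0,
                   table: ResidueTable | None = None) -> pd.DataFrame:
    """Deconvoluted peak list (mz, intensity, charge) for simulated products.

    ``products`` is an identification table (``sequence``, ``terminus5``,
    ``terminus3``, ``abundance``); each product yields one peak per charge,
    with m/z jittered by Normal(0, ppm_jitter) ppm.  With zero jitter,
    matching the peaks back recovers every product at 0 ppm.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for row in products.itertuples(index=False):
        seq = parse_sequence(str(row.sequence), terminus5=row.terminus5,
                             terminus3=row.terminus3, table=table)
        m = neutral_mass(seq, table=table)
        for z in charges:
            center = mz(m, z)
            jitter = rng.normal(0.0, ppm_jitter) if ppm_jitter > 0 else 0.0
            rows.append({
                "mz": center * (1.0 + jitter * 1e-6),
                "intensity": float(getattr(row, "abundance", 1.0)),
                "charge": z,
            })
    return pd.DataFrame(rows, columns=["mz", "intensity", "charge"])


def write_simulation(sim: SimulatedDigest, outdir: str | Path) -> list[Path]:
    """Write per-replicate identification CSVs plus the ground truth.

    Emits ``ids_rep<k>.csv`` per replicate, ``ids_all.csv``,
    ``ground_truth.csv`` and ``config.json``; returns the paths written.
    Fixed config (incl. seed) gives byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for rep, grp in sim.ids.groupby("replicate"):
        p = outdir / f"ids_rep{rep}.csv"
        grp.to_csv(p, index=False, float_format="%.10g")
        paths.append(p)
    p = outdir / "ids_all.csv"
    sim.ids.to_csv(p, index=False, float_format="%.10g")
    paths.append(p)
    p = outdir / "ground_truth.csv"
    sim.truth.to_csv(p, index=False, float_format="%.10g")
    paths.append(p)
    cfg = {
        "parent": serialize_sequence(sim.config.parent),
        "parent_id": sim.config.parent.id,
        "terminus5": sim.config.parent.terminus5,
        "terminus3": sim.config.parent.terminus3,
        "model": sim.config.model.to_dict(),
        "n_molecules": sim.config.n_molecules,
        "noise_sigma": sim.config.noise_sigma,
        "n_replicates": sim.config.n_replicates,
        "min_detectable_length": sim.config.min_detectable_length,
        "seed": sim.config.seed,
        "anchored": sim.config.anchored,
    }
    p = outdir / "config.json"
    with open(p, "w") as fh:
        json.dump(cfg, fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths.append(p)
    return paths
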