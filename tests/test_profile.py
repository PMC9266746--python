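"""Product placement and the per-bond cleavage-efficiency statistic."""

import math
import random

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import oracles
from rnasespec import (CleavageModel, aggregate, bond_efficiencies, categorize,
                       expected_abundances, parse_sequence, place_products,
                       read_identifications)
from rnasespec.digest import bond_probabilities
from test_digest import random_model


def ids_frame(rows, **common):
    defaults = {"terminus5": "hydroxyl", "terminus3": "cyclic_phosphate",
                "replicate": 1}
    defaults.update(common)
    return pd.DataFrame([{**defaults, **r} for r in rows])


def noiseless_placements(parent, model, n=1000.0, min_length=1):
    """Anchored placements straight from the noiseless expectations."""
    ea = expected_abundances(parent, model, n)
    ea = ea[ea["length"] >= min_length]
    return pd.DataFrame({
        "start": ea["start"], "end": ea["end"],
        "abundance": ea["expected_count"], "replicate": 1,
        "sequence": ea["sequence"], "n_placements": 1,
    })


class TestPlacement:
    def test_unique_products_place_at_known_positions(self, probe):
        ids = ids_frame([{"sequence": "UUGAGA", "abundance": 10.0},
                         {"sequence": "UUUGAGA", "abundance": 5.0},
                         {"sequence": "UACACCCGUAGGGCU", "abundance": 7.0}])
        placed, unmapped = place_products(probe, ids)
        assert len(unmapped) == 0
        spans = {r.sequence: (r.start, r.end) for r in placed.itertuples()}
        assert spans == {"UUGAGA": (26, 31), "UUUGAGA": (25, 31),
                         "UACACCCGUAGGGCU": (11, 25)}

    def test_mononucleotide_g_places_eight_ways_split(self, probe):
        placed, _ = place_products(probe, ids_frame([{"sequence": "G",
                                                      "abundance": 8.0}]),
                                   mode="split")
        assert sorted(placed["start"]) == [1, 7, 18, 21, 22, 23, 28, 30]
        assert all(placed["abundance"] == 1.0)

    def test_unique_only_excludes_ambiguous(self, probe):
        placed, unmapped = place_products(
            probe, ids_frame([{"sequence": "G", "abundance": 8.0},
                              {"sequence": "UUGAGA", "abundance": 1.0}]),
            mode="unique_only")
        assert len(placed) == 1 and placed.iloc[0]["sequence"] == "UUGAGA"
        assert len(unmapped) == 1 and "ambiguous" in unmapped.iloc[0]["reason"]

    def test_absent_product_reported_unmapped(self, probe):
        placed, unmapped = place_products(
            probe, ids_frame([{"sequence": "AAAAAA", "abundance": 1.0}]))
        assert len(placed) == 0
        assert unmapped.iloc[0]["reason"] == "not a substring of parent"

    def test_anchor_is_validated(self, probe):
        ids = ids_frame([{"sequence": "UUGAGA", "abundance": 1.0, "start": 3}])
        placed, unmapped = place_products(probe, ids)
        assert len(placed) == 0 and "anchor" in unmapped.iloc[0]["reason"]

    def test_modified_codes_match_exactly(self):
        parent = parse_sequence("G[m5C]UACU")
        placed, _ = place_products(parent, ids_frame([
            {"sequence": "[m5C]U", "abundance": 2.0}]))
        assert list(placed["start"]) == [2]  # does not also match the plain CU? none here
        placed2, unmapped2 = place_products(parent, ids_frame([
            {"sequence": "CU", "abundance": 2.0}]))
        assert list(placed2["start"]) == [5]


class TestBondEfficiencies:
    def test_worked_example_eighty_percent(self):
        """Cut-end products of 80 on each side of bond 3 plus a spanning
        product of 20 give 100*80/(80+20) = 80."""
        parent = parse_sequence("ACGUAC")
        placements = pd.DataFrame({
            "start": [1, 4, 1], "end": [3, 6, 6],
            "abundance": [80.0, 80.0, 20.0], "replicate": 1,
            "sequence": ["ACG", "UAC", "ACGUAC"], "n_placements": 1,
        })
        be = bond_efficiencies(parent, placements)
        row = be[be["bond"] == 3].iloc[0]
        assert row["x"] == 80.0 and row["y"] == 20.0
        assert row["efficiency"] == pytest.approx(80.0)
        assert row["category"] == "efficient"

    def test_no_coverage_is_undefined_not_zero(self):
        parent = parse_sequence("ACGU")
        placements = pd.DataFrame({"start": [1], "end": [2], "abundance": [5.0],
                                   "replicate": 1, "sequence": ["AC"],
                                   "n_placements": 1})
        be = bond_efficiencies(parent, placements)
        assert math.isnan(be[be["bond"] == 3].iloc[0]["efficiency"])
        assert be[be["bond"] == 3].iloc[0]["category"] is None
        # bond 2 is covered (spanned by nothing, but AC ends there)
        assert be[be["bond"] == 2].iloc[0]["efficiency"] == 100.0

    def test_half_cut_bond_scores_exactly_fifty(self):
        parent = parse_sequence("ACGU")
        model = CleavageModel(p={("C", "G"): 0.5})
        be = bond_efficiencies(parent, noiseless_placements(parent, model))
        assert be[be["bond"] == 2].iloc[0]["efficiency"] == pytest.approx(50.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_estimator_is_exact_on_noiseless_data(self, seed):
        """On noiseless expected abundances with full detection the statistic
        returns exactly 100*p at every covered bond (oracle enumeration)."""
        rng = random.Random(seed)
        n = rng.randint(2, 8)
        parent = parse_sequence("".join(rng.choice("ACGU") for _ in range(n)))
        model = random_model(rng)
        be = bond_efficiencies(parent, noiseless_placements(parent, model))
        probs = bond_probabilities(parent, model)
        oracle = oracles.brute_force_efficiencies(
            n, oracles.brute_force_fragments(n, list(probs), 1000.0))
        for row in be.itertuples():
            if row.bond in oracle:
                assert row.efficiency == pytest.approx(100.0 * probs[row.bond - 1],
                                                       abs=1e-9)
                assert row.efficiency == pytest.approx(oracle[row.bond], abs=1e-9)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 10**6), st.floats(0.01, 1000.0))
    def test_scale_invariance(self, seed, scale):
        """Multiplying every abundance by a constant leaves efficiencies
        unchanged: the statistic is a pure ratio."""
        rng = random.Random(seed)
        parent = parse_sequence("".join(rng.choice("ACGU") for _ in range(7)))
        model = random_model(rng, grid=(0.1, 0.4, 0.7))
        pl = noiseless_placements(parent, model)
        scaled = pl.assign(abundance=pl["abundance"] * scale)
        a = bond_efficiencies(parent, pl)["efficiency"]
        b = bond_efficiencies(parent, scaled)["efficiency"]
        assert np.allclose(a, b, equal_nan=True)

    def test_detection_floor_bias_is_halved_by_two_end_average(self):
        """Dropping mononucleotides (the undetectable-UMP case) only biases
        bonds adjacent to length-1 products, and only through the missing
        end term: the other end still contributes, so the estimate stays
        within half the full effect."""
        parent = parse_sequence("GCUUG")
        model = CleavageModel(p={("C", "U"): 0.9, ("U", "U"): 0.5})
        full = bond_efficiencies(parent, noiseless_placements(parent, model))
        floored = bond_efficiencies(parent,
                                    noiseless_placements(parent, model, min_length=2))
        # bond 3 (UpU) loses the single-U products on both sides
        exact = full[full["bond"] == 3].iloc[0]["efficiency"]
        biased = floored[floored["bond"] == 3].iloc[0]["efficiency"]
        assert exact == pytest.approx(50.0, abs=1e-9)
        assert biased < exact
        # bond 1 (GpC, p=0) is untouched by the floor
        assert floored[floored["bond"] == 1].iloc[0]["efficiency"] == pytest.approx(
            full[full["bond"] == 1].iloc[0]["efficiency"], abs=1e-12)


class TestCategories:
    @pytest.mark.parametrize("eff,label", [
        (0.0, "extremely_low"), (1.25, "extremely_low"), (4.999, "extremely_low"),
        (5.0, "low"), (24.999, "low"),
        (25.0, "moderate"), (50.0, "moderate"),
        (50.001, "efficient"), (100.0, "efficient"),
    ])
    def test_boundaries(self, eff, label):
        assert categorize(eff) == label

    def test_undefined_is_uncategorized(self):
        assert categorize(float("nan")) is None

    def test_extremely_low_range_example(self):
        """Replicates at 1.0 and 1.5 percent average to an extremely-low call."""
        assert categorize(np.mean([1.0, 1.5])) == "extremely_low"


class TestAggregate:
    def _tables(self, effs, npn="CpU", bond=5):
        out = []
        for rep, e in enumerate(effs, 1):
            out.append(pd.DataFrame([{
                "replicate": rep, "bond": bond, "npn": npn, "codes": npn,
                "x": e, "y": 100 - e, "efficiency": float(e),
                "category": categorize(float(e))}]))
        return out

    def test_range_across_replicates(self):
        prof = aggregate(self._tables([80.0, 90.0, 100.0]))
        row = prof.per_npn.iloc[0]
        assert (row["min"], row["max"]) == (80.0, 100.0)
        assert row["mean"] == pytest.approx(90.0)
        assert row["sd"] == pytest.approx(10.0)
        assert row["category"] == "efficient"

    def test_single_replicate_sd_not_available(self):
        prof = aggregate(self._tables([42.0]))
        row = prof.per_npn.iloc[0]
        assert math.isnan(row["sd"])
        assert (row["min"], row["max"]) == (42.0, 42.0)

    def test_min_le_mean_le_max(self, probe, mc1_like_model):
        pl = noiseless_placements(probe, mc1_like_model)
        prof = aggregate([bond_efficiencies(probe, pl, replicate=1)])
        ok = prof.per_npn.dropna(subset=["mean"])
        assert (ok["min"] <= ok["mean"] + 1e-12).all()
        assert (ok["mean"] <= ok["max"] + 1e-12).all()

    def test_modified_dinucleotides_aggregate_separately(self):
        parent = parse_sequence("A[m5C]UACU")
        model = CleavageModel(p={("C", "U"): 0.8}, overrides={("m5C", "U"): 0.4})
        be = bond_efficiencies(parent, noiseless_placements(parent, model))
        prof = aggregate([be.assign(replicate=1)])
        classes = dict(zip(prof.per_npn["codes"], prof.per_npn["mean"]))
        assert classes["[m5C]pU"] == pytest.approx(40.0, abs=1e-9)
        assert classes["CpU"] == pytest.approx(80.0, abs=1e-9)


class TestReadIdentifications:
    def test_negative_abundance_reports_row(self, tmp_path):
        path = tmp_path / "ids.csv"
        path.write_text("sequence,terminus5,terminus3,abundance,replicate\n"
                        "UUGAGA,hydroxyl,cyclic_phosphate,5.0,1\n"
                        "CUUUG,hydroxyl,cyclic_phosphate,-3,1\n")
        with pytest.raises(ValueError, match="row 3"):
            read_identifications(path)

    def test_missing_column_reported(self, tmp_path):
        path = tmp_path / "ids.csv"
        path.write_text("sequence,abundance\nUUGAGA,5.0\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_identifications(path)
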