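import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pairfish as pf
from pairfish.config import PairingParams


class TestPairDistance:
    @pytest.mark.parametrize("x,z,expected", [
        (3.0, 4.0, 5.0),                 # 3-4-5 triangle
        (1.2, 0.0, 1.2),                 # same plane: reduces to 2D
        (0.8, 2 * 0.5, math.sqrt(0.64 + 1.00)),  # 2-plane offset, 0.5 um step
    ])
    def test_closed_form(self, x, z, expected):
        assert pf.pair_distance(x, z) == pytest.approx(expected, abs=1e-12)

    def test_negative_component_rejected(self):
        with pytest.raises(ValueError):
            pf.pair_distance(-0.1, 0.5)

    @settings(derandomize=True, max_examples=200)
    @given(st.lists(st.floats(-10, 10), min_size=6, max_size=6))
    def test_equivalent_to_full_3d_euclidean(self, coords):
        # in-plane separation plus axial offset is the full 3D distance
        a, b = np.array(coords[:3]), np.array(coords[3:])
        x = math.hypot(a[0] - b[0], a[1] - b[1])
        z = abs(a[2] - b[2])
        assert pf.pair_distance(x, z) == pytest.approx(
            float(np.linalg.norm(a - b)), abs=1e-9)


def _spots(rows):
    cols = ["spot_id", "x_um", "y_um", "z_plane", "integrated_intensity"]
    df = pd.DataFrame(rows, columns=cols)
    df["outlier"] = False
    return df


class TestClassifyPairing:
    def test_single_focus_is_paired_at_distance_zero(self):
        call = pf.classify_pairing(_spots([("s1", 1.0, 1.0, 4, 100.0)]), 0.5)
        assert call["state"] == "paired"
        assert call["distance_um"] == 0.0

    def test_two_foci_same_plane_distance_is_lateral(self):
        call = pf.classify_pairing(
            _spots([("s1", 1.0, 1.0, 4, 100.0), ("s2", 1.9, 1.0, 4, 95.0)]),
            0.5)
        assert call["state"] == "unpaired"
        assert call["distance_um"] == pytest.approx(0.9)

    def test_z_offset_enters_through_plane_index(self):
        call = pf.classify_pairing(
            _spots([("s1", 1.0, 1.0, 4, 100.0), ("s2", 1.8, 1.0, 6, 95.0)]),
            0.5)
        assert call["distance_um"] == pytest.approx(math.sqrt(0.64 + 1.0))

    def test_four_foci_excluded(self):
        rows = [(f"s{i}", 1.0 + 0.5 * i, 1.0, 4, 100.0) for i in range(4)]
        call = pf.classify_pairing(_spots(rows), 0.5)
        assert call["state"] == "excluded"
        assert call["exclusion_reason"] == "too_many_foci"

    def test_three_foci_default_ambiguous(self):
        rows = [(f"s{i}", 1.0 + 0.6 * i, 1.0, 4, 100.0) for i in range(3)]
        call = pf.classify_pairing(_spots(rows), 0.5)
        assert call["exclusion_reason"] == "ambiguous_three_foci"

    def test_three_foci_keep_policy_scores_two_brightest(self):
        rows = [("s0", 1.0, 1.0, 4, 200.0), ("s1", 2.0, 1.0, 4, 190.0),
                ("s2", 3.0, 1.0, 4, 20.0)]
        call = pf.classify_pairing(_spots(rows), 0.5,
                                   PairingParams(three_foci_policy="keep"))
        assert call["state"] == "unpaired"
        assert call["distance_um"] == pytest.approx(1.0)

    def test_no_signal_flagged(self):
        call = pf.classify_pairing(_spots([]), 0.5)
        assert call["exclusion_reason"] == "no_signal"

    def test_order_invariant(self):
        rows = [("s1", 1.0, 1.0, 4, 100.0), ("s2", 1.9, 1.3, 5, 95.0)]
        a = pf.classify_pairing(_spots(rows), 0.5)
        b = pf.classify_pairing(_spots(rows[::-1]), 0.5)
        assert a == b

    def test_outlier_punctum_dropped_before_counting(self):
        df = _spots([("s1", 1.0, 1.0, 4, 100.0), ("s2", 1.9, 1.0, 4, 2000.0)])
        df.loc[df["spot_id"] == "s2", "outlier"] = True
        call = pf.classify_pairing(df, 0.5)
        assert call["state"] == "paired"


class TestOutlierFilter:
    def test_uniform_cohort_unflagged(self):
        flags = pf.intensity_outlier_filter([100.0] * 20)
        assert not flags.any()

    def test_tenfold_punctum_flagged(self):
        vals = [100.0] * 19 + [1000.0]
        flags = pf.intensity_outlier_filter(vals, k=3.0)
        assert flags[-1] and flags[:-1].sum() == 0

    def test_small_cohort_disables_filter(self):
        flags = pf.intensity_outlier_filter([100.0, 1000.0], min_cohort=10)
        assert not flags.any()

    def test_realistic_cohort_no_false_flags(self):
        # lognormal spread typical of the generator's amplitudes: no flags
        rng = np.random.default_rng(0)
        vals = 1000 * rng.lognormal(0, 0.2, 200)
        assert not pf.intensity_outlier_filter(vals, k=3.0).any()


def _norm_inputs():
    spots = pd.DataFrame({
        "spot_id": ["g1", "g2", "c1", "c2", "c3"],
        "cell_id": ["germ1", "germ2", "cy1", "cy2", "cy3"],
        "field": ["f0"] * 5,
        "integrated_intensity": [50.0, 120.0, 100.0, 100.0, 100.0],
    })
    calls = pd.DataFrame({
        "cell_id": ["germ1", "germ2", "cy1", "cy2", "cy3"],
        "field": ["f0"] * 5,
        "stage": ["GB", "GB", "CySC", "CySC", "CySC"],
        "state": ["unpaired", "paired", "paired", "paired", "paired"],
    })
    return spots, calls


class TestNormalizeToCysc:
    def test_per_punctum_is_ratio_to_reference(self):
        spots, calls = _norm_inputs()
        norm = pf.normalize_to_cysc(spots, calls, seed=0)
        germ = norm[norm["cell_id"] == "germ1"]
        assert germ["per_punctum"].iloc[0] == pytest.approx(0.5)

    def test_paired_per_allele_is_half_per_punctum(self):
        spots, calls = _norm_inputs()
        norm = pf.normalize_to_cysc(spots, calls, seed=0)
        paired = norm[norm["cell_id"] == "germ2"].iloc[0]
        unpaired = norm[norm["cell_id"] == "germ1"].iloc[0]
        assert paired["per_allele"] == pytest.approx(paired["per_punctum"] / 2)
        assert unpaired["per_allele"] == pytest.approx(unpaired["per_punctum"])

    def test_same_seed_same_reference_picks(self):
        spots, calls = _norm_inputs()
        a = pf.normalize_to_cysc(spots, calls, seed=5)
        b = pf.normalize_to_cysc(spots, calls, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_fewer_than_two_paired_cyscs_is_an_error(self):
        spots, calls = _norm_inputs()
        calls.loc[calls["stage"] == "CySC", "state"] = "unpaired"
        with pytest.raises(ValueError, match="f0"):
            pf.normalize_to_cysc(spots, calls, seed=0)


def test_ratio_missing_state_partial_result():
    norm = pd.DataFrame({
        "stage": ["GB"] * 12, "state": ["paired"] * 12,
        "per_punctum": np.full(12, 1.0), "per_allele": np.full(12, 0.5),
    })
    r = pf.paired_unpaired_ratio(norm, stage="GB", n_boot=50)
    assert r["missing_state"] == "unpaired"
    assert math.isnan(r["per_punctum_ratio"])


def test_summarize_pairing_all_paired_distances_zero():
    calls = pd.DataFrame({
        "cell_id": [f"c{i}" for i in range(8)],
        "stage": ["GSC"] * 8, "state": ["paired"] * 8,
        "distance_um": [0.0] * 8, "exclusion_reason": ["none"] * 8,
    })
    out = pf.summarize_pairing_by_stage(calls)
    row = out.iloc[0]
    assert row["paired_fraction"] == 1.0
    assert row["distance_max"] == 0.0


def test_summarize_pairing_excluded_never_in_fraction():
    calls = pd.DataFrame({
        "cell_id": [f"c{i}" for i in range(6)],
        "stage": ["GB"] * 6,
        "state": ["paired", "unpaired", "unpaired", "excluded", "excluded",
                  "paired"],
        "distance_um": [0.0, 1.0, 1.5, np.nan, np.nan, 0.0],
        "exclusion_reason": ["none", "none", "none", "too_many_foci",
                             "ambiguous_three_foci", "none"],
    })
    row = pf.summarize_pairing_by_stage(calls).iloc[0]
    assert row["n_scored"] == 4
    assert row["paired_fraction"] == pytest.approx(0.5)
    assert row["n_excluded"] == 2
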