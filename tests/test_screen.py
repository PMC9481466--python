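"""Robust-Z statistics, hit calling, replicate concordance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import ldscreen as ld
from ldscreen.screen import (MAD_SCALE, PUBLISHED_SCREEN_CONSTANTS, ScreenConstants,
                             TargetingScreenModel, mad, replicate_correlation,
                             robust_z, score_screen)


def brute_median(values):
    s = sorted(values)
    n = len(s)
    mid = n // 2
    return s[mid] if n % 2 else (s[mid - 1] + s[mid]) / 2


def brute_mad(values):
    m = brute_median(values)
    return brute_median([abs(v - m) for v in values])


def brute_robust_z(x, values):
    return (x - brute_median(values)) / (MAD_SCALE * brute_mad(values))


def well_frame(x, role="library", replicate=1, plate=1):
    """Build a minimal well table from an array of readouts."""
    return pd.DataFrame({
        "plate": plate, "replicate": replicate,
        "well": [f"W{i:05d}" for i in range(len(x))],
        "gene": [f"g{i}" for i in range(len(x))],
        "dsrna_id": [f"d{i}" for i in range(len(x))],
        "role": role, "x_i": x,
        "cell_count": 800, "rel_ld_area": 0.06,
    })


class TestMadRobustZ:
    def test_hand_values(self):
        assert mad([1, 2, 3, 4, 5]) == 1.0
        assert mad([7, 7, 7]) == 0.0
        assert mad([3.5]) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mad([])

    def test_zero_mad_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            robust_z(1.0, ScreenConstants(0.0, 0.0))

    def test_screen_center_is_zero(self):
        assert robust_z(2.147287, PUBLISHED_SCREEN_CONSTANTS) == 0.0

    def test_one_robust_sd_above_center_is_one(self):
        x = PUBLISHED_SCREEN_CONSTANTS.median + MAD_SCALE * PUBLISHED_SCREEN_CONSTANTS.mad
        assert robust_z(x, PUBLISHED_SCREEN_CONSTANTS) == pytest.approx(1.0, abs=1e-12)

    def test_hand_arithmetic_example(self):
        c = ScreenConstants(median=brute_median([1, 2, 3, 4, 5]),
                            mad=brute_mad([1, 2, 3, 4, 5]))
        assert robust_z(5, c) == pytest.approx(2 / 1.4826, abs=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-1e3, 1e3), min_size=1, max_size=40))
    def test_matches_brute_force(self, values):
        assert mad(values) == pytest.approx(brute_mad(values), abs=1e-12)
        if brute_mad(values) > 0:
            c = ScreenConstants(median=float(np.median(values)), mad=mad(values))
            assert robust_z(values[0], c) == pytest.approx(
                brute_robust_z(values[0], values), abs=1e-9)

    def test_affine_equivariance(self):
        rng = np.random.default_rng(8)
        x = rng.normal(2, 0.3, 200)
        a, b = 3.7, -1.2
        z0 = robust_z(x, ScreenConstants(float(np.median(x)), mad(x)))
        y = a * x + b
        z1 = robust_z(y, ScreenConstants(float(np.median(y)), mad(y)))
        np.testing.assert_allclose(z0, z1, atol=1e-10)

    def test_mad_consistent_for_gaussian(self):
        rng = np.random.default_rng(9)
        x = rng.normal(0, 2.5, 100_000)
        assert MAD_SCALE * mad(x) == pytest.approx(2.5, rel=0.02)


class TestModelFit:
    def test_identical_wells_raise_degenerate_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            score_screen(well_frame(np.full(20, 2.0)))

    def test_shift_leaves_z_unchanged_when_recomputed(self):
        rng = np.random.default_rng(10)
        x = rng.normal(2.1, 0.2, 100)
        z0 = score_screen(well_frame(x)).frame["z_targeting"].to_numpy()
        z1 = score_screen(well_frame(x + 0.7)).frame["z_targeting"].to_numpy()
        np.testing.assert_allclose(z0, z1, atol=1e-10)

    def test_packaged_constants_used_when_given(self):
        res = score_screen(well_frame(np.array([2.147287, 2.0, 2.3])),
                           constants=PUBLISHED_SCREEN_CONSTANTS)
        tc = res.constants["targeting"]
        assert (tc.median, tc.mad) == (2.147287, 0.113917)
        row = res.frame.set_index("dsrna_id").loc["d0"]
        assert row["z_targeting"] == 0.0

    def test_replicates_averaged_per_dsrna(self):
        f1 = well_frame(np.array([1.0, 2.0]), replicate=1)
        f2 = well_frame(np.array([3.0, 2.5]), replicate=2)
        model = TargetingScreenModel(pd.concat([f1, f2], ignore_index=True))
        res = model.fit(constants=PUBLISHED_SCREEN_CONSTANTS)
        combined = res.frame.set_index("dsrna_id")["x"]
        assert combined["d0"] == pytest.approx(2.0)
        assert combined["d1"] == pytest.approx(2.25)

    def test_all_undefined_rejected(self):
        frame = well_frame(np.full(5, np.nan))
        with pytest.raises(ValueError):
            score_screen(frame)

    def test_summary_mentions_constants_and_hits(self):
        res = score_screen(well_frame(np.random.default_rng(3).normal(2.1, 0.2, 50)),
                           constants=PUBLISHED_SCREEN_CONSTANTS)
        res.call_hits()
        text = res.summary()
        assert "2.147287" in text and "0.113917" in text
        assert "decrease hits" in text


class TestHitCalls:
    def _results(self, z_values, cell_z=None, ld_z=None, genes=None):
        n = len(z_values)
        c = PUBLISHED_SCREEN_CONSTANTS
        x = c.median + np.asarray(z_values) * MAD_SCALE * c.mad
        frame = well_frame(x)
        if genes is not None:
            frame["gene"] = genes
        res = score_screen(frame, constants=c)
        if cell_z is not None:
            res.frame["z_cell_count"] = cell_z
        if ld_z is not None:
            res.frame["z_ld_area"] = ld_z
        return res

    def test_strict_cutoffs(self):
        res = self._results([-5.5, -2.5, 2.5, 2.500001, -2.500001, 0.0],
                            cell_z=np.zeros(6), ld_z=np.zeros(6))
        out = res.call_hits()
        calls = out.set_index("dsrna_id")["hit_call"]
        assert calls["d0"] == "decrease"       # Rab1-like score
        assert calls["d1"] == "none"           # exactly -2.5 is not a hit
        assert calls["d2"] == "none"
        assert calls["d3"] == "increase"
        assert calls["d4"] == "decrease"
        assert calls["d5"] == "none"

    def test_cell_death_demotes_but_keeps_z(self):
        res = self._results([-3.0, -3.0], cell_z=[-3.0, 0.0], ld_z=[0.0, 0.0])
        out = res.call_hits()
        rows = out.set_index("dsrna_id")
        assert rows.loc["d0", "flag_cell_death"] and rows.loc["d0", "hit_call"] == "none"
        assert rows.loc["d0", "z_targeting"] == pytest.approx(-3.0)
        assert rows.loc["d1", "hit_call"] == "decrease"

    def test_small_ld_and_category_flags(self):
        res = self._results([-4.0, 4.0], cell_z=[0.0, 0.0], ld_z=[-4.0, 0.0],
                            genes=["gA", "RpL3"])
        out = res.call_hits(excluded_categories={"RpL3"})
        rows = out.set_index("dsrna_id")
        assert rows.loc["d0", "flag_small_ld"] and rows.loc["d0", "hit_call"] == "none"
        assert rows.loc["d1", "flag_excluded_category"]
        assert rows.loc["d1", "hit_call"] == "none"

    def test_gene_level_takes_largest_abs_z(self):
        res = self._results([1.0, -3.5], genes=["gX", "gX"],
                            cell_z=[0.0, 0.0], ld_z=[0.0, 0.0])
        res.call_hits()
        gl = res.gene_level().set_index("gene")
        assert gl.loc["gX", "z_targeting"] == pytest.approx(-3.5)


class TestReplicateCorrelation:
    def _paired(self, x1, x2):
        f1 = well_frame(np.asarray(x1), replicate=1)
        f2 = well_frame(np.asarray(x2), replicate=2)
        return pd.concat([f1, f2], ignore_index=True)

    def test_identical_replicates(self):
        x = np.random.default_rng(0).normal(2, 0.2, 10)
        assert replicate_correlation(self._paired(x, x)) == pytest.approx(1.0)

    def test_anticorrelated_replicates(self):
        x = np.random.default_rng(0).normal(0, 1, 10)
        assert replicate_correlation(self._paired(x, -x)) == pytest.approx(-1.0)

    def test_too_few_pairs_rejected(self):
        x = np.array([1.0, 2.0])
        with pytest.raises(ValueError):
            replicate_correlation(self._paired(x, x))

    def test_matches_variance_ratio_prediction(self):
        """Closed-form oracle: r = gene_var / (gene_var + well_var)."""
        noise = ld.ScreenNoiseModel()
        plates = ld.generate_screen_layout(3, 384, 2,
                                           [f"g{i}" for i in range(1100)], seed=14)
        effects = ld.make_effects(plates, seed=14)
        wells = ld.simulate_screen_wells(plates, effects, noise, seed=14)
        r = replicate_correlation(wells, library_only=True)
        assert r == pytest.approx(noise.expected_replicate_r, abs=0.05)


class TestPower:
    def test_planted_strong_decreases_are_recalled(self):
        """Knockdowns that cut the ratio by >= 40% are found >= 90% of the time."""
        plates = ld.generate_screen_layout(1, 384, 2,
                                           [f"g{i}" for i in range(300)], seed=77)
        effects = ld.make_effects(plates, decrease_fraction=0.08,
                                  decrease_multiplier=0.6, seed=77)
        wells = ld.simulate_screen_wells(plates, effects, seed=77)
        out = score_screen(wells).call_hits()
        planted = {d for d, e in effects.items()
                   if e.true_ratio < 0.9 * 2.15 and d.startswith("ds_g")}
        assert planted
        called = set(out[out["hit_call"] == "decrease"]["dsrna_id"])
        assert len(planted & called) / len(planted) >= 0.9
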