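import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from unidose import (
    GammaCriteria,
    VolumeGrid,
    dose_at_volume,
    dvh_curve,
    gamma_passing_rate,
    mape,
    report_cohort,
)

from gamma_oracle import brute_gamma


def _smooth_pair(seed, n=12, noise=0.04):
    rng = np.random.default_rng(seed)
    base = ndimage.gaussian_filter(rng.uniform(0.2, 1.0, (n, n, n)), 1.5)
    base /= base.max()
    ev = np.maximum(base * (1 + rng.normal(0, noise, base.shape)), 0)
    return VolumeGrid(base, 2.0), VolumeGrid(ev, 2.0)


class TestGamma:
    def test_identity_passes_everywhere(self):
        ref, _ = _smooth_pair(0)
        res = gamma_passing_rate(ref, ref)
        assert res.gpr == 100.0
        assert np.nanmax(res.gamma_map) == 0.0

    def test_two_percent_global_scaling_passes(self):
        ref, _ = _smooth_pair(1)
        res = gamma_passing_rate(ref, ref.like(1.02 * ref.values))
        assert res.gpr == 100.0

    def test_matches_exhaustive_oracle(self):
        crit = GammaCriteria()
        for seed in range(3):
            ref, ev = _smooth_pair(seed, noise=0.05)
            res = gamma_passing_rate(ref, ev, crit)
            gpr_b, gam_b = brute_gamma(ref, ev, crit)
            assert abs(res.gpr - gpr_b) <= 0.1
            gam = res.gamma_map[~np.isnan(res.gamma_map)]
            np.testing.assert_allclose(gam, gam_b, atol=1e-10)

    def test_loosening_criteria_never_decreases_gpr(self):
        ref, ev = _smooth_pair(5, noise=0.10)
        base = gamma_passing_rate(ref, ev, GammaCriteria(3, 2, 10)).gpr
        looser_dd = gamma_passing_rate(ref, ev, GammaCriteria(5, 2, 10)).gpr
        looser_dta = gamma_passing_rate(ref, ev, GammaCriteria(3, 4, 10)).gpr
        assert looser_dd >= base
        assert looser_dta >= base

    def test_low_dose_threshold_excludes_voxels(self):
        ref, ev = _smooth_pair(2)
        res = gamma_passing_rate(ref, ev)
        assert res.n_evaluated == int(
            np.sum(ref.values >= 0.1 * ref.values.max())
        )
        assert np.isnan(res.gamma_map[ref.values < 0.1 * ref.values.max()]).all()

    def test_all_zero_reference_rejected(self):
        z = VolumeGrid(np.zeros((6, 6, 6)), 2.0)
        with pytest.raises(ValueError, match="all-zero"):
            gamma_passing_rate(z, z)


class TestDoseAtVolume:
    def _grid(self, values):
        return VolumeGrid(values, 2.0)

    def test_uniform_roi(self):
        dose = self._grid(np.full((5, 5, 4), 60.0))
        mask = self._grid(np.ones((5, 5, 4)))
        assert dose_at_volume(dose, mask, 95) == 60.0
        assert dose_at_volume(dose, mask, 5) == 60.0

    def test_counting_oracle_one_to_hundred(self):
        dose = self._grid(np.arange(1.0, 101.0).reshape(5, 5, 4))
        mask = self._grid(np.ones((5, 5, 4)))
        # 95 voxels receive at least 6 Gy
        assert dose_at_volume(dose, mask, 95) == 6.0
        assert dose_at_volume(dose, mask, 100) == 1.0
        assert dose_at_volume(dose, mask, 1) == 100.0

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_order_statistic_monotonicity(self, seed):
        rng = np.random.default_rng(seed)
        dose = self._grid(rng.uniform(0, 70, (6, 6, 6)))
        mask = self._grid((rng.uniform(size=(6, 6, 6)) < 0.6).astype(float))
        if not (mask.values > 0.5).any():
            return
        d95 = dose_at_volume(dose, mask, 95)
        d50 = dose_at_volume(dose, mask, 50)
        d5 = dose_at_volume(dose, mask, 5)
        d2 = dose_at_volume(dose, mask, 2)
        assert d95 <= d50 <= d5 <= d2

    def test_empty_mask_rejected(self):
        dose = self._grid(np.ones((4, 4, 4)))
        with pytest.raises(ValueError, match="empty ROI"):
            dose_at_volume(dose, self._grid(np.zeros((4, 4, 4))), 95)


class TestDVH:
    def test_uniform_dose_is_step_function(self):
        dose = VolumeGrid(np.full((4, 4, 4), 30.0), 2.0)
        mask = VolumeGrid(np.ones((4, 4, 4)), 2.0)
        c = dvh_curve(dose, mask, bin_gy=1.0)
        assert np.all(c.volume_fraction[c.dose_gy <= 30.0] == 1.0)
        assert np.all(c.volume_fraction[c.dose_gy > 30.0] == 0.0)

    def test_starts_at_one_and_non_increasing(self, rng):
        dose = VolumeGrid(rng.uniform(0, 60, (8, 8, 8)), 2.0)
        mask = VolumeGrid(np.ones((8, 8, 8)), 2.0)
        c = dvh_curve(dose, mask)
        assert c.volume_fraction[0] == 1.0
        assert np.all(np.diff(c.volume_fraction) <= 0)

    def test_consistent_with_dose_at_volume(self, rng):
        bin_gy = 0.25
        for _ in range(20):
            dose = VolumeGrid(rng.uniform(0, 60, (8, 8, 8)), 2.0)
            mask = VolumeGrid((rng.uniform(size=(8, 8, 8)) < 0.5).astype(float), 2.0)
            if not (mask.values > 0.5).any():
                continue
            c = dvh_curve(dose, mask, bin_gy=bin_gy)
            for x in (95, 50, 5):
                dx = dose_at_volume(dose, mask, x)
                # at dose level Dx%, the curve must still hold >= x% volume
                j = np.searchsorted(c.dose_gy, dx - bin_gy)
                assert c.volume_fraction[j] >= x / 100.0 - 1e-12


class TestMAPE:
    def test_identical_pairs_give_zero(self):
        assert mape([(60.0, 60.0), (30.0, 30.0)], 60.0) == 0.0

    def test_single_case_hand_calculation(self):
        assert mape([(63.0, 60.0)], 60.0) == pytest.approx(5.0)

    def test_two_case_mean(self):
        assert mape([(63.0, 60.0), (66.0, 60.0)], 60.0) == pytest.approx(7.5)

    def test_symmetry_and_nonnegativity(self, rng):
        pairs = [tuple(p) for p in rng.uniform(10, 70, (6, 2))]
        flipped = [(b, a) for a, b in pairs]
        assert mape(pairs, 60.0) == pytest.approx(mape(flipped, 60.0))
        assert mape(pairs, 60.0) >= 0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            mape([], 60.0)
        with pytest.raises(ValueError):
            mape([(1.0, 2.0)], 0.0)


class TestReport:
    def test_single_case_summary_and_recompute(self, small_case, small_label, tmp_path):
        noisy = small_label.like(
            np.maximum(small_label.values * 1.03 - 0.1, 0.0)
        )
        df, summary = report_cohort(
            [small_case], [{"pred": noisy, "opt": small_label, "label": small_label}]
        )
        assert len(df) == 1
        gpr_cols = [c for c in df.columns if c.startswith("gpr_")]
        assert len(gpr_cols) == 3
        for c in gpr_cols:
            assert 0.0 <= df[c].iloc[0] <= 100.0
            assert summary.loc[c, "mean"] == pytest.approx(df[c].iloc[0])
        # independent recomputation from the CSV round-trip
        df.to_csv(tmp_path / "m.csv", index=False)
        back = pd.read_csv(tmp_path / "m.csv")
        assert back[gpr_cols].mean().tolist() == pytest.approx(
            [summary.loc[c, "mean"] for c in gpr_cols]
        )

    def test_missing_dose_skipped_with_warning(self, small_case, small_label):
        with pytest.warns(UserWarning, match="missing dose"):
            df, _ = report_cohort(
                [small_case], [{"pred": small_label, "opt": None, "label": small_label}]
            )
        assert "gpr_pred_vs_opt" not in df.columns or df["gpr_pred_vs_opt"].isna().all()
        assert df["gpr_pred_vs_label"].iloc[0] == 100.0
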