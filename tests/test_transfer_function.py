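"""WA-PLS calibration, prediction, amalgamation and bootstrap validation."""

import numpy as np
import pandas as pd
import pytest

from sedapipe.synthetic_data import SimulationConfig, simulate_calibration
from sedapipe.transfer_function import (
    amalgamate_low_counts,
    bootstrap_validate,
    wapls_fit,
    wapls_predict,
)


def classical_wa_inverse_deshrink(Y, x):
    """Independent oracle: weighted averaging with weighted inverse deshrinking."""
    Y = np.asarray(Y, dtype=float)
    P = Y / Y.sum(axis=1, keepdims=True)
    Yt = np.sqrt(P)
    x = np.asarray(x, dtype=float)
    optima = (Yt * x[:, None]).sum(axis=0) / Yt.sum(axis=0)
    wa = (Yt * optima[None, :]).sum(axis=1) / Yt.sum(axis=1)
    w = Yt.sum(axis=1)
    w = w / w.sum()
    # weighted simple regression of x on the WA estimate
    mx, mw = np.sum(w * x), np.sum(w * wa)
    b = np.sum(w * (wa - mw) * (x - mx)) / np.sum(w * (wa - mw) ** 2)
    a = mx - b * mw
    return a + b * wa


def calib(seed=3, **kw):
    cfg = SimulationConfig(seed=seed)
    for k, v in kw.items():
        setattr(cfg.calibration, k, v)
    return simulate_calibration(cfg)


class TestAmalgamation:
    taxa = ["a", "b"]

    def frame(self, totals):
        data = [[t // 2, t - t // 2] for t in totals]
        ids = [f"d{i}" for i in range(len(totals))]
        return (
            pd.DataFrame(data, index=ids, columns=self.taxa),
            pd.Series([10.0 * (i + 1) for i in range(len(totals))], index=ids),
        )

    def test_counts_above_minimum_unchanged(self):
        counts, depths = self.frame([50, 60])
        merged, _, amap = amalgamate_low_counts(counts, depths, 40)
        assert list(merged.sum(axis=1)) == [50, 60]
        assert all(len(v) == 1 for v in amap.values())

    def test_low_counts_merge_with_nearer_neighbour(self):
        counts, depths = self.frame([25, 20, 50])
        merged, _, amap = amalgamate_low_counts(counts, depths, 40)
        assert list(merged.sum(axis=1)) == [45, 50]
        assert amap["d0+d1"] == ["d0", "d1"]

    def test_unreachable_minimum_collapses_with_warning(self):
        counts, depths = self.frame([5, 6, 7])
        with pytest.warns(UserWarning, match="below min_count"):
            merged, _, _ = amalgamate_low_counts(counts, depths, 40)
        assert len(merged) == 1
        assert merged.sum().sum() == 18

    def test_exception_sample_may_stay_low(self):
        counts, depths = self.frame([36, 60])
        merged, _, _ = amalgamate_low_counts(counts, depths, 40, exceptions={"d0"})
        assert len(merged) == 2


class TestWAPLSFit:
    def test_one_component_equals_classical_wa(self, rng):
        for _ in range(10):
            n, m = int(rng.integers(10, 40)), int(rng.integers(4, 12))
            Y = rng.poisson(5.0, size=(n, m)) + 1
            x = rng.uniform(5, 15, n)
            model = wapls_fit(Y, x, n_components=1)
            expect = classical_wa_inverse_deshrink(Y, x)
            np.testing.assert_allclose(model.fitted, expect, atol=1e-8)

    def test_identical_assemblages_predict_mean(self):
        Y = np.tile([3.0, 5.0, 2.0], (8, 1))
        x = np.arange(8, dtype=float)
        model = wapls_fit(Y, x, n_components=2)
        np.testing.assert_allclose(model.fitted, np.full(8, x.mean()), atol=1e-10)

    def test_second_component_never_hurts_apparent_fit(self, rng):
        for seed in range(5):
            cal, T, _, _ = calib(seed=seed + 1, n_sites=80, n_taxa=12)
            m1 = wapls_fit(cal, T, n_components=1)
            m2 = wapls_fit(cal, T, n_components=2)
            assert m2.apparent_rmse <= m1.apparent_rmse + 1e-10

    def test_high_r2_on_gaussian_responses(self):
        cal, T, _, _ = calib(n_sites=200, count_size=400)
        model = wapls_fit(cal, T, n_components=2)
        assert model.apparent_r2 > 0.9

    def test_too_few_taxa_is_error(self):
        with pytest.raises(ValueError, match="fewer taxa"):
            wapls_fit(np.ones((5, 1)), np.arange(5.0), n_components=2)


class TestWAPLSPredict:
    def test_calibration_site_reproduces_fitted_value(self):
        cal, T, _, _ = calib(n_sites=60)
        model = wapls_fit(cal, T)
        pred = wapls_predict(model, cal)
        np.testing.assert_allclose(pred, model.fitted, atol=1e-10)

    def test_scale_invariance(self):
        cal, T, fos, _ = calib(n_sites=60)
        model = wapls_fit(cal, T)
        p1 = wapls_predict(model, fos)
        p2 = wapls_predict(model, fos * 17)
        np.testing.assert_allclose(p1, p2, atol=1e-10)

    def test_unknown_taxa_warned_and_ignored(self):
        cal, T, fos, _ = calib(n_sites=60)
        model = wapls_fit(cal, T)
        fos2 = fos.copy()
        fos2["mystery"] = 3
        with pytest.warns(UserWarning, match="mystery"):
            p = wapls_predict(model, fos2)
        np.testing.assert_allclose(p, wapls_predict(model, fos), atol=1e-10)

    def test_all_unknown_taxa_is_error(self):
        cal, T, _, _ = calib(n_sites=60)
        model = wapls_fit(cal, T)
        alien = pd.DataFrame({"x1": [3], "x2": [5]})
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="no calibration taxon"):
                wapls_predict(model, alien)

    def test_temperature_recovery_along_known_trajectory(self):
        cal, T, fos, T_true = calib(n_sites=200, count_size=300)
        model = wapls_fit(cal, T)
        pred = wapls_predict(model, fos)
        rmse = np.sqrt(np.mean((pred - T_true) ** 2))
        assert rmse < 1.0
        assert abs(np.mean(pred - T_true)) < 0.5  # reconstruction bias


class TestBootstrap:
    def test_fixed_seed_reproducible(self):
        cal, T, fos, _ = calib(n_sites=50, n_taxa=10)
        a = bootstrap_validate(cal, T, fossil=fos, n_boot=25, seed=7)
        b = bootstrap_validate(cal, T, fossil=fos, n_boot=25, seed=7)
        assert a["RMSEP"] == b["RMSEP"]
        np.testing.assert_array_equal(a["eSEP"], b["eSEP"])

    def test_single_cycle_flagged_degenerate(self):
        cal, T, fos, _ = calib(n_sites=50, n_taxa=10)
        with pytest.warns(UserWarning, match="degenerate"):
            out = bootstrap_validate(cal, T, fossil=fos, n_boot=1, seed=7)
        assert np.isnan(out["eSEP"]).all()

    def test_esep_exceeds_rmsep(self):
        cal, T, fos, _ = calib(n_sites=60, n_taxa=10)
        out = bootstrap_validate(cal, T, fossil=fos, n_boot=50, seed=7)
        assert (out["eSEP"] >= out["RMSEP"] - 1e-12).all()
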