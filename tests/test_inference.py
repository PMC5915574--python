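import numpy as np
import pytest
from scipy import stats

from dseqc.core import compute_dse_timeseries
from dseqc.inference import (
    HIQR0,
    IQR0,
    NullModel,
    dvars_test,
    estimate_mu0,
    estimate_sigma0_sq,
    fit_null,
    flag_scans,
    infer_dvars,
    standardized_variants,
    z_scores,
)
from dseqc.simulation import SimulationSpec, simulate_null

from .conftest import make_scaled


def _null_dvars_sq(seed=0, I=2000, T=600, lo=200.0, hi=500.0):
    ds = simulate_null(SimulationSpec(I=I, T=T, sigma_min=lo, sigma_max=hi, seed=seed))
    return (np.diff(ds.data, axis=1) ** 2).mean(axis=0), ds


def test_iqr0_constant():
    assert IQR0 == pytest.approx(stats.norm.ppf(0.75) - stats.norm.ppf(0.25))
    assert round(IQR0, 3) == 1.349
    assert HIQR0 == IQR0 / 2


class TestEstimateMu0:
    def test_constant_series(self):
        x = np.full(10, 7.5)
        assert estimate_mu0(x, method="mean_dvars2") == 7.5
        assert estimate_mu0(x, method="median_dvars2") == 7.5

    def test_null_recovery_median_dvars2(self):
        dvars_sq, ds = _null_dvars_sq(seed=1, I=10_000, T=1200)
        est = estimate_mu0(dvars_sq, method="median_dvars2")
        assert est == pytest.approx(ds.true_mu0, rel=0.01)

    def test_voxelwise_mean_recovery(self):
        # Monte-Carlo check that no extra scale factor is needed: the mean of
        # voxelwise robust differenced-data variances matches 2*mean(sigma^2)
        dvars_sq, ds = _null_dvars_sq(seed=2, I=3000, T=800)
        diffdata = np.diff(ds.data, axis=1)
        est = estimate_mu0(dvars_sq, diffdata=diffdata, method="mean_voxel_sigmaD")
        assert est == pytest.approx(ds.true_mu0, rel=0.02)

    def test_single_voxel_consistency(self, rng):
        sigma_d = 3.0
        diff = rng.standard_normal((1, 20_000)) * sigma_d
        est = estimate_mu0(np.ones(5), diffdata=diff, method="median_voxel_sigmaD")
        assert est == pytest.approx(sigma_d**2, rel=0.03)

    def test_voxelwise_needs_diffdata(self):
        with pytest.raises(ValueError, match="diffdata"):
            estimate_mu0(np.ones(5), method="mean_voxel_sigmaD")

    def test_degenerate_null(self):
        with pytest.raises(ValueError, match="degenerate null"):
            estimate_mu0(np.ones(6), diffdata=np.ones((3, 6)), method="median_voxel_sigmaD")

    def test_unknown_method(self):
        with pytest.raises(ValueError):
            estimate_mu0(np.ones(6), method="mode")


class TestEstimateSigma0Sq:
    @pytest.mark.parametrize("var_method,d", [
        ("sample", 1.0), ("iqr", 1.0), ("iqr", 0.5), ("iqr", 1 / 3), ("iqr", 0.25),
        ("hiqr", 1.0), ("hiqr", 0.5), ("hiqr", 1 / 3), ("hiqr", 0.25),
    ])
    def test_null_recovery_all_estimators(self, var_method, d):
        dvars_sq, ds = _null_dvars_sq(seed=3, I=10_000, T=1200)
        est = estimate_sigma0_sq(dvars_sq, var_method=var_method, d=d)
        assert est == pytest.approx(ds.true_sigma0_sq, rel=0.15)

    def test_hiqr_ignores_upper_contamination(self, rng):
        x = rng.chisquare(50, size=501) * 10
        clean = estimate_sigma0_sq(x, var_method="hiqr", d=1.0)
        x_spiked = x.copy()
        top = x_spiked > np.quantile(x_spiked, 0.55)
        x_spiked[top] *= 100.0  # alter only values above the median
        spiked = estimate_sigma0_sq(x_spiked, var_method="hiqr", d=1.0)
        assert spiked == pytest.approx(clean, rel=1e-12)

    def test_degenerate_null(self):
        with pytest.raises(ValueError, match="degenerate null"):
            estimate_sigma0_sq(np.full(10, 3.0), var_method="hiqr", d=1.0)

    def test_invalid_d(self):
        with pytest.raises(ValueError):
            estimate_sigma0_sq(np.arange(10.0), var_method="iqr", d=0.4)

    def test_short_series(self):
        with pytest.raises(ValueError):
            estimate_sigma0_sq(np.arange(3.0))


class TestNullModel:
    def test_nu_definition(self):
        null = NullModel(mu0=10.0, sigma0_sq=8.0)
        assert null.nu == pytest.approx(2 * 100 / 8)

    def test_validation(self):
        with pytest.raises(ValueError):
            NullModel(mu0=-1.0, sigma0_sq=1.0)
        with pytest.raises(ValueError):
            NullModel(mu0=1.0, sigma0_sq=0.0)


class TestDvarsTest:
    def test_statistic_at_null_mean_equals_nu(self):
        null = NullModel(mu0=5.0, sigma0_sq=2.0)
        x, p = dvars_test(np.array([5.0]), null)
        assert x[0] == pytest.approx(null.nu)

    def test_p_uniform_under_null(self):
        dvars_sq, ds = _null_dvars_sq(seed=4, I=10_000, T=1200)
        null = fit_null(dvars_sq)
        _, p = dvars_test(dvars_sq, null)
        ks = stats.kstest(p, "uniform")
        assert ks.pvalue > 0.01

    def test_nu_hat_near_voxel_count(self):
        dvars_sq, ds = _null_dvars_sq(seed=5, I=2000, T=600)
        null = fit_null(dvars_sq)
        assert 0.5 <= null.nu / 2000 <= 2.0

    def test_two_sided_detects_down_spikes(self):
        dvars_sq, _ = _null_dvars_sq(seed=6)
        null = fit_null(dvars_sq)
        low = np.array([null.mu0 / 3.0])
        _, p1 = dvars_test(low, null)
        _, p2 = dvars_test(low, null, two_sided=True)
        assert p1[0] > 0.5 and p2[0] < 0.05


class TestZScores:
    def test_p_half_is_zero(self):
        null = NullModel(mu0=1.0, sigma0_sq=1.0)
        assert z_scores(np.array([0.5]), np.array([1.0]), null)[0] == pytest.approx(0.0)

    def test_underflow_fallback(self):
        null = NullModel(mu0=100.0, sigma0_sq=25.0)
        x = np.array([100.0 + 40 * 5.0])
        z = z_scores(np.array([0.0]), x, null)
        assert z[0] == pytest.approx(40.0)

    def test_monotone_decreasing_in_p(self, rng):
        null = NullModel(mu0=1.0, sigma0_sq=1.0)
        p = np.sort(rng.uniform(1e-12, 1 - 1e-12, 100))
        z = z_scores(p, np.ones(100), null)
        assert (np.diff(z) < 0).all()

    def test_agreement_with_fallback_in_tail(self):
        # one-sided p and the moment fallback agree to ~2 decimals for
        # moderate tail Z once nu is large enough that the chi-squared skew
        # (sqrt(8/nu)) is negligible against the 0.02 tolerance
        null = NullModel(mu0=1e8, sigma0_sq=2e8)  # nu = 1e8
        sigma0 = np.sqrt(null.sigma0_sq)
        for z_true in (4.5, 5.0, 6.0, 7.0, 7.9):
            x = np.array([null.mu0 + z_true * sigma0])
            _, p = dvars_test(x, null)
            z = z_scores(p, x, null)
            assert z[0] == pytest.approx(z_true, abs=0.02)


class TestStandardizedVariants:
    def _null(self, mu0=4.0):
        return NullModel(mu0=mu0, sigma0_sq=1.0)

    def test_null_point(self, rng):
        dse = compute_dse_timeseries(make_scaled(rng.standard_normal((50, 30))))
        null = self._null(mu0=float(4 * dse.D[3]))
        v = standardized_variants(dse, null)
        assert v["delta_pct_dvar"][3] == pytest.approx(0.0, abs=1e-12)
        assert v["rel_dvars"][3] == pytest.approx(1.0)

    def test_pct_dvar_definition(self, rng):
        dse = compute_dse_timeseries(make_scaled(rng.standard_normal((50, 30))))
        A = dse.averages()["A"]
        dse.D = np.full_like(dse.D, A / 2)
        v = standardized_variants(dse, self._null())
        np.testing.assert_allclose(v["pct_dvar"], 50.0)

    def test_delta_pct_example(self, rng):
        # D_t = 0.7016 A with null floor mu0/(4A) = 0.2896 -> 41.20% excess
        dse = compute_dse_timeseries(make_scaled(rng.standard_normal((50, 30))))
        A = dse.averages()["A"]
        dse.D[0] = 0.7016 * A
        null = NullModel(mu0=4 * A * 0.2896, sigma0_sq=1.0)
        v = standardized_variants(dse, null)
        assert v["delta_pct_dvar"][0] == pytest.approx(41.20, abs=0.005)

    def test_delta_identity(self, rng):
        # delta = pct - 100 mu0/(4A), exactly
        dse = compute_dse_timeseries(make_scaled(rng.standard_normal((40, 25))))
        null = self._null(mu0=2.345)
        v = standardized_variants(dse, null)
        A = dse.averages()["A"]
        np.testing.assert_allclose(v["delta_pct_dvar"],
                                   v["pct_dvar"] - 100 * null.mu0 / (4 * A),
                                   rtol=0, atol=1e-10)

    def test_zero_data_fatal(self):
        dse = compute_dse_timeseries(make_scaled(np.zeros((3, 5))))
        with pytest.raises(ValueError):
            standardized_variants(dse, self._null())


class TestFlags:
    def _result(self, p, delta):
        import pandas as pd

        from dseqc.inference import InferenceResult

        n = len(p)
        tab = pd.DataFrame({
            "t": np.arange(1, n + 1),
            "p_value": p,
            "delta_pct_dvar": delta,
        })
        return InferenceResult(table=tab, null=NullModel(mu0=1, sigma0_sq=1))

    def test_no_flags(self):
        flags = flag_scans(self._result(np.full(10, 0.9), np.full(10, 50.0)))
        assert not flags["flag_statistical"].any()
        assert not flags["flag_practical"].any()

    def test_both_flags(self):
        p = np.array([1e-12, 0.5])
        delta = np.array([41.2, 0.0])
        flags = flag_scans(self._result(p, delta))
        assert flags["flag_statistical"][0] and flags["flag_practical"][0]
        assert flags.loc[0, "t"] == 1 and flags.loc[0, "t_next"] == 2

    def test_statistical_only(self):
        flags = flag_scans(self._result(np.array([1e-12, 0.5]), np.array([4.95, 0.0])))
        assert flags["flag_statistical"][0] and not flags["flag_practical"][0]

    def test_bonferroni_threshold(self):
        n = 100
        p = np.full(n, 0.04)  # significant uncorrected, not after Bonferroni
        flags = flag_scans(self._result(p, np.full(n, 50.0)), alpha=0.05)
        assert not flags["flag_statistical"].any()

    def test_practical_subset_property(self, rng):
        for _ in range(20):
            p = rng.uniform(0, 0.02, 50)
            delta = rng.normal(5, 4, 50)
            flags = flag_scans(self._result(p, delta))
            assert (flags["flag_practical"] <= flags["flag_statistical"]).all()

    def test_only_bonferroni(self):
        with pytest.raises(ValueError):
            flag_scans(self._result(np.array([0.5, 0.5]), np.zeros(2)), correction="fdr")


class TestEndToEnd:
    def test_infer_dvars_null_calibration(self):
        ds = simulate_null(SimulationSpec(I=4000, T=600, seed=11))
        dse = compute_dse_timeseries(ds.centered())
        res = infer_dvars(dse, diffdata=np.diff(ds.centered().values, axis=1))
        tab = res.table
        assert ((tab["p_value"] >= 0) & (tab["p_value"] <= 1)).all()
        assert (tab["flag_practical"] <= tab["flag_statistical"]).all()
        # rejections at uncorrected alpha within 3 MC standard errors
        for alpha in (0.01, 0.05):
            rate = (tab["p_value"] <= alpha).mean()
            se = np.sqrt(alpha * (1 - alpha) / len(tab))
            assert rate <= alpha + 3 * se

    def test_robust_to_spikes(self):
        # Robustness of the default moment estimators to upward spikes.
        # The median mu0 moves <5% even with 10% of pairs spiked.  The
        # hIQR variance has bounded influence: quantile arithmetic puts its
        # shift at ~+2% for 3% contamination and ~+20% for 10% (each spiked
        # value drags Q1 and the median up by one quantile step), while the
        # non-robust sample variance explodes by orders of magnitude.
        ds = simulate_null(SimulationSpec(I=4000, T=600, seed=12))
        dvars_sq = (np.diff(ds.data, axis=1) ** 2).mean(axis=0)
        rng = np.random.default_rng(12)

        def contaminate(frac):
            spiked = dvars_sq.copy()
            idx = rng.choice(len(spiked), size=int(frac * len(spiked)), replace=False)
            spiked[idx] *= 8.0
            return spiked

        mu_c = estimate_mu0(dvars_sq)
        s_c = estimate_sigma0_sq(dvars_sq)

        heavy = contaminate(0.10)
        assert abs(estimate_mu0(heavy) - mu_c) / mu_c < 0.05
        rel_hiqr = abs(estimate_sigma0_sq(heavy) - s_c) / s_c
        rel_sample = abs(np.var(heavy, ddof=1) - np.var(dvars_sq, ddof=1)) \
            / np.var(dvars_sq, ddof=1)
        assert rel_hiqr < 0.35
        assert rel_sample > 100 * rel_hiqr

        light = contaminate(0.03)
        assert abs(estimate_sigma0_sq(light) - s_c) / s_c < 0.05

    def test_flagged_pairs_listing(self):
        ds = simulate_null(SimulationSpec(I=2000, T=300, seed=13))
        data = ds.data.copy()
        data[:, 150] += np.sign(data[:, 150]) * 400.0  # big artifact at scan 151
        dse = compute_dse_timeseries(make_scaled(data - data.mean(axis=1, keepdims=True)))
        res = infer_dvars(dse)
        flagged = res.flagged_pairs
        assert (150, 151) in flagged and (151, 152) in flagged
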