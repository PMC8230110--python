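"""Statistics layer: oracle equivalence and planted-effect recovery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as spstats

from pulsewalk.stats import (
    bh_adjust,
    block_reliability,
    channelwise_contrast,
    delta_correlation,
    gesd_outliers,
    paired_ttest,
    residualize,
    stroop_change,
)
from pulsewalk.types import DataError, ParameterError


# --- independent oracles -------------------------------------------------

def bh_oracle(p):
    """Textbook Benjamini-Hochberg step-up, by sorting and cumulative min."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = m - rank_from_end
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj


def gesd_oracle(x, alpha=0.05, max_out=None):
    """Independent generalized-ESD written directly from the definition."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if max_out is None:
        max_out = int(np.ceil(0.1 * n))
    max_out = min(max_out, n - 2)
    idx = np.arange(n)
    removed, flags = [], []
    for i in range(1, max_out + 1):
        mu = x[idx].mean()
        s = x[idx].std(ddof=1)
        if s == 0:
            break
        j = idx[np.argmax(np.abs(x[idx] - mu))]
        R = abs(x[j] - mu) / s
        nn = n - i + 1
        t = spstats.t.ppf(1 - alpha / (2 * nn), nn - 2)
        lam = (nn - 1) * t / np.sqrt((nn - 2 + t * t) * nn)
        removed.append(j)
        flags.append(R > lam)
        idx = idx[idx != j]
    k = 0
    for i, f in enumerate(flags):
        if f:
            k = i + 1
    return sorted(removed[:k])


# --- residualization -----------------------------------------------------

class TestResidualize:
    def test_orthogonal_covariate_is_identity(self, rng):
        y = rng.normal(size=40)
        z = rng.normal(size=40)
        z = z - z.mean()
        y_o = y - np.dot(y, z) / np.dot(z, z) * z  # orthogonalize
        adj = residualize(y_o, z)
        assert np.allclose(adj, y_o, atol=1e-10)

    def test_fully_explained_collapses_to_grand_mean(self, rng):
        pase = rng.uniform(50, 300, size=30)
        values = 2.0 * pase
        adj = residualize(values, pase)
        assert np.allclose(adj, values.mean(), atol=1e-8)

    def test_planted_confound_removed(self, rng):
        """A linear covariate effect is removed; the group difference between
        adjusted halves recovers the planted offset."""
        n = 200
        group = np.repeat([0.0, 1.0], n // 2)
        pase = rng.normal(150, 50, n)
        y = 0.6 + 0.05 * group + 0.002 * (pase - 150) + rng.normal(0, 0.01, n)
        adj = residualize(y, pase)
        diff = adj[group == 1].mean() - adj[group == 0].mean()
        assert diff == pytest.approx(0.05, abs=0.01)

    def test_collinear_covariates_rejected(self, rng):
        z = rng.normal(size=30)
        with pytest.raises(ParameterError):
            residualize(rng.normal(size=30), np.column_stack([z, z]))


# --- GESD ----------------------------------------------------------------

class TestGesd:
    def test_single_planted_outlier(self, rng):
        x = rng.normal(size=50)
        x = np.clip(x, -2.5, 2.5)  # ensure no accidental extremes
        x[7] = 100.0
        assert gesd_outliers(x) == [7]

    def test_two_planted_outliers(self, rng):
        x = np.clip(rng.normal(size=50), -2.5, 2.5)
        x[3], x[11] = 50.0, -40.0
        assert gesd_outliers(x, max_out=2) == [3, 11]

    def test_constant_plus_jitter_is_clean(self, rng):
        x = 5.0 + 1e-9 * rng.normal(size=30)
        assert gesd_outliers(x) == []

    def test_matches_independent_oracle(self, rng):
        """Exact index agreement with a from-the-definition implementation
        on 1,000 random instances (mixture of clean and contaminated)."""
        for trial in range(1000):
            n = int(rng.integers(8, 40))
            x = rng.normal(size=n)
            k = int(rng.integers(0, 3))
            if k:
                pos = rng.choice(n, size=k, replace=False)
                x[pos] += rng.choice([-1, 1], size=k) * rng.uniform(5, 60, size=k)
            assert gesd_outliers(x) == gesd_oracle(x)

    def test_small_sample_rejected(self):
        with pytest.raises(ParameterError):
            gesd_outliers(np.arange(4.0))


# --- paired t ------------------------------------------------------------

class TestPairedT:
    def test_identical_vectors(self, rng):
        x = rng.normal(size=10)
        res = paired_ttest(x, x.copy())
        assert res.statistic == 0.0 and res.p_raw == 1.0
        assert res.df == 9

    def test_constant_nonzero_difference_is_error(self):
        with pytest.raises(DataError):
            paired_ttest(np.array([2.0, 3.0, 4.0, 5.0]), np.array([1.0, 2.0, 3.0, 4.0]))

    def test_matches_formula_and_scipy(self, rng):
        x = rng.normal(size=25)
        y = rng.normal(0.3, 1.0, size=25)
        res = paired_ttest(x, y)
        d = x - y
        t_formula = d.mean() / (d.std(ddof=1) / np.sqrt(25))
        assert res.statistic == pytest.approx(t_formula, abs=1e-10)
        t_sp, p_sp = spstats.ttest_rel(x, y)
        assert res.statistic == pytest.approx(t_sp, abs=1e-10)
        assert res.p_raw == pytest.approx(p_sp, abs=1e-10)


# --- reliability & delta correlations ------------------------------------

class TestCorrelations:
    def test_reliability_extremes(self, rng):
        x = rng.normal(size=19)
        assert block_reliability(x, x)[0] == pytest.approx(1.0)
        assert block_reliability(x, -x)[0] == pytest.approx(-1.0)

    def test_proportional_deltas_give_unit_r(self, rng):
        d = rng.normal(size=19)
        res = delta_correlation(d, 3.0 * d)
        assert res["r"] == pytest.approx(1.0)

    def test_partial_with_no_covariates_equals_pearson(self, rng):
        a, b = rng.normal(size=20), rng.normal(size=20)
        plain = delta_correlation(a, b)
        empty = delta_correlation(a, b, covariates=np.empty((20, 0)))
        assert plain["r"] == empty["r"]
        assert plain["method"] == empty["method"] == "pearson"

    def test_shared_covariate_kills_partial_r(self, rng):
        """Deltas driven entirely by a shared covariate: the raw correlation
        is ~ -1 but the partial correlation drops to sampling noise around 0
        (sd ~ 1/sqrt(n) of the residual noise)."""
        z = rng.normal(size=60)
        a = 2.0 * z + 1e-6 * rng.normal(size=60)
        b = -1.5 * z + 1e-6 * rng.normal(size=60)
        raw = delta_correlation(a, b)
        res = delta_correlation(a, b, covariates=z)
        assert raw["r"] < -0.99
        assert abs(res["r"]) < 4 / np.sqrt(60)
        assert res["p"] > 0.05

    def test_partial_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        a, b, z = rng.normal(size=40), rng.normal(size=40), rng.normal(size=40)
        b = b + 0.5 * z
        a = a + 0.5 * z
        res = delta_correlation(a, b, covariates=z)
        df = pd.DataFrame(dict(a=a, b=b, z=z))
        ref = pingouin.partial_corr(df, x="a", y="b", covar="z")
        assert res["r"] == pytest.approx(float(ref["r"].iloc[0]), abs=1e-8)
        assert res["p"] == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-8)

    def test_outlier_removal_logged(self, rng):
        d1 = np.clip(rng.normal(size=19), -2.5, 2.5)
        d2 = 0.8 * d1 + 0.3 * np.clip(rng.normal(size=19), -2.5, 2.5)
        d2[4] = 50.0
        res = delta_correlation(d1, d2, drop_outliers=True)
        assert res["outliers_removed"] == [4]
        assert res["n"] == 18

    def test_planted_correlation_recovered_large_n(self):
        """Cohort-planted r = 0.47 estimated within 0.05 at n = 1000."""
        from pulsewalk.synth import CohortParams, simulate_cohort

        _, _, truth = simulate_cohort(
            CohortParams(seed=11, n_participants=1000), with_recordings=False
        )
        res = delta_correlation(truth.deltas["d_amp"].to_numpy(),
                                truth.deltas["d_rt_inhibition"].to_numpy())
        assert res["r"] == pytest.approx(0.47, abs=0.05)


# --- BH / channel maps ---------------------------------------------------

class TestFDR:
    def test_worked_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), 0.04)

    def test_matches_brute_force_oracle(self, rng):
        """Agreement with a sort-and-step oracle on 1,000 random p-vectors,
        including tied values."""
        for _ in range(1000):
            m = int(rng.integers(1, 60))
            p = rng.uniform(size=m)
            if rng.random() < 0.3 and m > 3:  # inject ties
                p[: m // 2] = p[0]
            assert np.allclose(bh_adjust(p), bh_oracle(p), atol=1e-12)

    @given(
        p_list=st.lists(st.floats(min_value=1e-12, max_value=1.0),
                        min_size=1, max_size=40)
    )
    @settings(derandomize=True, max_examples=100, deadline=None)
    def test_bh_property_matches_oracle(self, p_list):
        p = np.array(p_list)
        got = bh_adjust(p)
        assert np.allclose(got, bh_oracle(p), atol=1e-12)
        assert (got >= p - 1e-15).all() and (got <= 1.0 + 1e-15).all()

    def test_identical_conditions_yield_no_discoveries(self, rng):
        a = pd.DataFrame(rng.normal(0.6, 0.05, size=(10, 8)),
                         columns=[f"ch{i}" for i in range(8)])
        res = channelwise_contrast(a, a.copy())
        assert (res["t"] == 0).all()
        assert not res["significant"].any()

    def test_sparse_channels_excluded(self, rng):
        cols = [f"ch{i}" for i in range(4)]
        a = pd.DataFrame(rng.normal(size=(6, 4)), columns=cols)
        b = pd.DataFrame(rng.normal(size=(6, 4)), columns=cols)
        a.loc[a.index[2:], "ch3"] = np.nan  # only 2 paired rows remain
        res = channelwise_contrast(a, b)
        assert "ch3" not in set(res["channel_id"])
        assert res.attrs["skipped_channels"] == ["ch3"]

    def test_planted_effect_detected(self, rng):
        cols = [f"ch{i}" for i in range(10)]
        base = rng.normal(0.6, 0.05, size=(19, 10))
        a = pd.DataFrame(base, columns=cols)
        b = pd.DataFrame(base - 0.001 * rng.standard_normal((19, 10)), columns=cols)
        b[["ch0", "ch1"]] -= 0.08  # strong planted reduction in two channels
        res = channelwise_contrast(a, b).set_index("channel_id")
        assert res.loc["ch0", "significant"] and res.loc["ch1", "significant"]


# --- Stroop --------------------------------------------------------------

class TestStroopChange:
    def _tables(self, rng, n=19):
        """Participant tables whose means equal the study-population values."""
        means_t0 = dict(naming=31.52, reading=22.05, inhibition=58.21, switching=63.05)
        means_t12 = dict(naming=29.105, reading=21.26, inhibition=54.05, switching=56.63)
        noise = rng.normal(size=(n, 4))
        noise -= noise.mean(axis=0)  # exact sample means
        rt0 = pd.DataFrame({c: means_t0[c] + noise[:, i]
                            for i, c in enumerate(means_t0)})
        rt12 = pd.DataFrame({c: means_t12[c] + noise[:, i] * 0.9
                             for i, c in enumerate(means_t12)})
        err = pd.DataFrame(np.full((n, 4), 2.0), columns=list(means_t0))
        return rt0, rt12, err

    def test_inhibition_and_switching_worked_examples(self, rng):
        rt0, rt12, err = self._tables(rng)
        out = stroop_change(rt0, rt12, err, err.copy()).set_index("condition")
        assert out.loc["inhibition", "delta_rt"] == pytest.approx(4.16, abs=1e-9)
        assert out.loc["switching", "delta_rt"] == pytest.approx(6.42, abs=1e-9)

    def test_identical_tables_zero_change(self, rng):
        rt0, _, err = self._tables(rng)
        out = stroop_change(rt0, rt0.copy(), err, err.copy())
        assert np.allclose(out["delta_rt"], 0.0)

    def test_missing_condition_is_error(self, rng):
        rt0, rt12, err = self._tables(rng)
        with pytest.raises(DataError):
            stroop_change(rt0.drop(columns=["naming"]), rt12)

    def test_speed_accuracy_flag(self, rng):
        rt0, rt12, err = self._tables(rng)
        err12 = err + 5.0 + rng.normal(0, 0.1, size=err.shape)  # errors worsen
        out = stroop_change(rt0, rt12, err, err12).set_index("condition")
        assert out.loc["inhibition", "speed_accuracy_flag"]


# --- calibration of the planted regime ------------------------------------

class TestPlantedRegimeCalibration:
    def test_power_of_longitudinal_contrast(self):
        """Planted 0.61->0.55 decline (n=19) is detected at p < 0.001 in
        >= 80% of repetitions, the significance regime of the study."""
        from pulsewalk.synth import CohortParams, simulate_cohort

        hits = 0
        reps = 200
        for seed in range(reps):
            _, _, truth = simulate_cohort(CohortParams(seed=seed),
                                          with_recordings=False)
            amp = truth.amplitudes
            bw = amp[amp.condition == "BW"].pivot_table(
                index="participant_id", columns="timepoint", values="value"
            )
            res = paired_ttest(bw["T0"].to_numpy(), bw["T12"].to_numpy())
            hits += res.p_raw < 0.001
        assert hits / reps >= 0.80

    def test_type_one_error_under_null(self):
        """With no planted decline the paired test rejects at ~ alpha."""
        from pulsewalk.synth import CohortParams, simulate_cohort

        rejections = 0
        reps = 300
        for seed in range(reps):
            params = CohortParams(seed=10_000 + seed, amp_bw_t12=(0.61, 0.07))
            _, _, truth = simulate_cohort(params, with_recordings=False)
            amp = truth.amplitudes
            bw = amp[amp.condition == "BW"].pivot_table(
                index="participant_id", columns="timepoint", values="value"
            )
            res = paired_ttest(bw["T0"].to_numpy(), bw["T12"].to_numpy())
            rejections += res.p_raw < 0.05
        rate = rejections / reps
        mc_se = np.sqrt(0.05 * 0.95 / reps)
        assert rate == pytest.approx(0.05, abs=3 * mc_se)
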