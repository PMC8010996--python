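"""Mixed-model fertility derivation, standardization, cohort merging and
carrier contrasts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import recqtl
from recqtl.errors import IdMismatchError, InvalidConfigError, SingularDesignError
from recqtl.fertility import FIXED_FACTORS


def minimal_records(outcomes, bulls, herds=None):
    n = len(outcomes)
    return pd.DataFrame(
        {
            "outcome": outcomes,
            "bull": bulls,
            "herd": herds if herds is not None else ["h1"] * n,
            "month": ["m1"] * n,
            "parity": ["cow"] * n,
            "price": ["p1"] * n,
            "breed_combo": ["bb"] * n,
            "technician": ["t1"] * n,
        }
    )


def gls_blup_oracle(records, ratios):
    """Brute-force GLS/BLUP on the equivalent mixed model."""
    y = records["outcome"].to_numpy(dtype=float)
    herd_codes, herds = pd.factorize(records["herd"], sort=True)
    bull_codes, bulls = pd.factorize(records["bull"], sort=True)
    n = len(y)
    zh = np.zeros((n, len(herds)))
    zh[np.arange(n), herd_codes] = 1
    zs = np.zeros((n, len(bulls)))
    zs[np.arange(n), bull_codes] = 1
    x = np.ones((n, 1))  # intercept-only fixtures
    sig_h, sig_s = 1 / ratios["herd"], 1 / ratios["bull"]
    v = sig_h * zh @ zh.T + sig_s * zs @ zs.T + np.eye(n)
    vi = np.linalg.inv(v)
    b = np.linalg.solve(x.T @ vi @ x, x.T @ vi @ y)
    resid = y - x @ b
    s_hat = sig_s * zs.T @ vi @ resid
    h_hat = sig_h * zh.T @ vi @ resid
    return b, h_hat, s_hat, list(bulls)


class TestMme:
    def test_matches_gls_oracle(self, rng):
        outcomes = rng.integers(0, 2, size=24)
        bulls = [f"b{v}" for v in rng.integers(0, 4, size=24)]
        herds = [f"h{v}" for v in rng.integers(0, 3, size=24)]
        records = minimal_records(outcomes, bulls, herds)
        ratios = {"herd": 5.0, "bull": 7.0}
        res = recqtl.solve_nrr_mme(records, ratios)
        _, h_hat, s_hat, bull_order = gls_blup_oracle(records, ratios)
        mme_s = res.estimates.set_index("bull")["raw_effect"]
        for b, expected in zip(bull_order, s_hat):
            assert mme_s[b] == pytest.approx(expected, abs=1e-8)
        mme_h = res.herd_effects.set_index("herd")["effect"]
        for hname, expected in zip(sorted(set(herds)), h_hat):
            assert mme_h[hname] == pytest.approx(expected, abs=1e-8)

    def test_huge_ratio_shrinks_to_zero(self, rng):
        outcomes = rng.integers(0, 2, size=40)
        bulls = [f"b{v}" for v in rng.integers(0, 4, size=40)]
        res = recqtl.solve_nrr_mme(
            minimal_records(outcomes, bulls), {"herd": 1e8, "bull": 1e8}
        )
        assert np.abs(res.estimates["raw_effect"]).max() < 1e-4

    def test_tiny_ratio_recovers_bull_means(self):
        # balanced design: 10 records per bull, herd effects suppressed
        outcomes = [1] * 8 + [0] * 2 + [1] * 5 + [0] * 5 + [1] * 2 + [0] * 8
        bulls = ["a"] * 10 + ["b"] * 10 + ["c"] * 10
        res = recqtl.solve_nrr_mme(
            minimal_records(outcomes, bulls), {"herd": 1e8, "bull": 1e-6}
        )
        grand = np.mean(outcomes)
        eff = res.estimates.set_index("bull")["raw_effect"]
        assert eff["a"] == pytest.approx(0.8 - grand, abs=1e-3)
        assert eff["b"] == pytest.approx(0.5 - grand, abs=1e-3)
        assert eff["c"] == pytest.approx(0.2 - grand, abs=1e-3)

    def test_recovery_from_simulated_records(self):
        true_effects = {f"b{i}": v for i, v in enumerate(
            np.random.default_rng(1).normal(0, 0.3, size=40)
        )}
        records = recqtl.simulate_inseminations(true_effects, 500, seed=2)
        res = recqtl.solve_nrr_mme(records)
        eff = res.estimates.set_index("bull")["raw_effect"]
        est = np.array([eff[b] for b in true_effects])
        truth = np.array(list(true_effects.values()))
        rho = stats.spearmanr(truth, est).statistic
        assert rho > 0.8

    def test_invalid_variance_ratio(self):
        with pytest.raises(InvalidConfigError):
            recqtl.solve_nrr_mme(minimal_records([1, 0], ["a", "a"]), {"bull": -1})

    def test_singular_design_names_aliased(self):
        records = minimal_records([1, 0, 1, 0], ["a", "a", "b", "b"])
        records["month"] = ["m1", "m1", "m2", "m2"]
        records["technician"] = ["t1", "t1", "t2", "t2"]  # aliased with month
        with pytest.raises(SingularDesignError, match="technician"):
            recqtl.solve_nrr_mme(records)


class TestStandardize:
    def test_mean_100_sd_12(self, rng):
        est = pd.DataFrame({"bull": list("abcdef"), "raw_effect": rng.normal(size=6)})
        out = recqtl.standardize_fertility(est)
        assert out["fertility"].mean() == pytest.approx(100, abs=1e-9)
        assert out["fertility"].std(ddof=1) == pytest.approx(12, abs=1e-9)

    def test_idempotent_on_mean_sd(self, rng):
        est = pd.DataFrame({"bull": list("abcdefgh"), "raw_effect": rng.normal(size=8)})
        once = recqtl.standardize_fertility(est)
        twice = recqtl.standardize_fertility(once, column="fertility")
        assert np.allclose(once["fertility"], twice["fertility"])

    def test_outlier_boundary_strict(self):
        vals = np.array([100.0, 101, 99, 102, 98, 97, 103, 60.0])
        est = pd.DataFrame({"bull": [f"b{i}" for i in range(8)], "fertility": vals})
        mean, sd = vals.mean(), vals.std(ddof=1)
        k_exact = (mean - vals.min()) / sd
        kept, removed = recqtl.remove_low_outliers(est, k=k_exact)
        assert len(removed) == 0, "exactly -k SD is retained"
        kept, removed = recqtl.remove_low_outliers(est, k=k_exact - 0.01)
        assert list(removed["bull"]) == ["b7"]

    def test_zero_variance_errors(self):
        est = pd.DataFrame({"bull": ["a", "b"], "fertility": [1.0, 1.0]})
        with pytest.raises(InvalidConfigError):
            recqtl.remove_low_outliers(est)


class TestMergeCohorts:
    def test_each_cohort_standardized(self, rng):
        est = pd.DataFrame(
            {
                "bull": [f"b{i}" for i in range(40)],
                "fertility": np.r_[rng.normal(100, 12, 20), rng.normal(95, 30, 20)],
                "cohort": ["CH"] * 20 + ["DE-AT"] * 20,
            }
        )
        merged = recqtl.merge_cohorts(est)
        for cohort, grp in merged.groupby("cohort"):
            assert grp["phenotype"].mean() == pytest.approx(0, abs=1e-9)
            assert grp["phenotype"].std(ddof=1) == pytest.approx(1, abs=1e-9)

    def test_single_cohort_plain_zscore(self, rng):
        v = rng.normal(50, 5, size=10)
        est = pd.DataFrame(
            {"bull": [f"b{i}" for i in range(10)], "fertility": v, "cohort": "CH"}
        )
        merged = recqtl.merge_cohorts(est)
        assert np.allclose(merged["phenotype"], (v - v.mean()) / v.std(ddof=1))

    def test_label_permutation_same_per_bull(self, rng):
        est = pd.DataFrame(
            {
                "bull": [f"b{i}" for i in range(20)],
                "fertility": rng.normal(size=20),
                "cohort": ["x"] * 10 + ["y"] * 10,
            }
        )
        a = recqtl.merge_cohorts(est).set_index("id")["phenotype"]
        shuffled = est.sample(frac=1, random_state=3)
        b = recqtl.merge_cohorts(shuffled).set_index("id")["phenotype"]
        for bull in est["bull"]:
            assert a[bull] == pytest.approx(b[bull])

    def test_singleton_cohort_errors(self):
        est = pd.DataFrame(
            {"bull": ["a", "b", "c"], "fertility": [1.0, 2.0, 3.0],
             "cohort": ["x", "x", "solo"]}
        )
        with pytest.raises(InvalidConfigError):
            recqtl.merge_cohorts(est)


class TestHomozygousLoad:
    def test_load_counting(self):
        statuses = [
            np.array([2, 0, 1]),
            np.array([2, 2, 0]),
            np.array([0, 0, 0]),
            np.array([2, 1, 1]),
            np.array([0, 0, 2]),
        ]
        load, tally = recqtl.homozygous_load(statuses)
        assert list(load) == [3, 1, 1]
        assert sum(tally.values()) == 3

    def test_all_zero_statuses(self):
        load, tally = recqtl.homozygous_load([np.zeros(4, int)] * 3)
        assert (load == 0).all()
        assert tally[0] == 4

    def test_mismatched_lengths_error(self):
        with pytest.raises(IdMismatchError):
            recqtl.homozygous_load([np.zeros(3, int), np.zeros(4, int)])


class TestLoadContrast:
    def test_identical_groups(self):
        g = np.array([1.0, 2.0, 3.0])
        t, p = recqtl.load_contrast_ttest(g, g)
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_summary_stats_from_cohort_contrast(self):
        """Printed NRR56 group summaries give t ~ 5.6, p of order 1e-8."""
        t, p = recqtl.welch_from_summary(1000, 65.48, 4.33, 322, 63.76, 4.89)
        assert t == pytest.approx(5.64, abs=0.05)
        assert 1e-9 < p < 1e-7

    def test_matches_permutation_oracle(self, rng):
        a = rng.normal(0.0, 1, size=12)
        b = rng.normal(1.0, 1, size=10)
        t, p = recqtl.load_contrast_ttest(a, b)
        pooled = np.r_[a, b]
        count = 0
        n_perm = 4000
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            pa, pb = perm[:12], perm[12:]
            tt = (pa.mean() - pb.mean()) / np.sqrt(
                pa.var(ddof=1) / 12 + pb.var(ddof=1) / 10
            )
            if abs(tt) >= abs(t):
                count += 1
        p_perm = count / n_perm
        assert p == pytest.approx(p_perm, abs=3 * np.sqrt(p_perm * (1 - p_perm) / n_perm) + 1e-3)

    def test_zero_variance_errors(self):
        with pytest.raises(InvalidConfigError):
            recqtl.load_contrast_ttest(np.ones(3), np.ones(4))


class TestHetVsNoncarrier:
    def test_recessive_qtl_gives_null_p(self):
        """Purely recessive effects leave the het contrast null-distributed."""
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            status = rng.choice([0, 1, 2], size=800, p=[0.67, 0.30, 0.03])
            y = rng.normal(size=800) - 0.8 * (status == 2)
            res = recqtl.het_vs_noncarrier_test(y, status)
            if res.p < 0.05:
                hits += 1
        assert hits <= 3  # binomial(10, 0.05) upper bound

    def test_additive_qtl_detected(self):
        detections = 0
        n_seeds = 10
        for seed in range(n_seeds):
            rng = np.random.default_rng(100 + seed)
            status = rng.choice([0, 1, 2], size=1000, p=[0.67, 0.30, 0.03])
            y = rng.normal(size=1000) - 0.4 * (status == 1) - 0.8 * (status == 2)
            res = recqtl.het_vs_noncarrier_test(y, status)
            if res.p < 0.05:
                detections += 1
        assert detections >= 8

    def test_requires_noncarriers(self):
        y = np.zeros(10)
        status = np.ones(10, dtype=int)
        with pytest.raises(InvalidConfigError):
            recqtl.het_vs_noncarrier_test(y, status)
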