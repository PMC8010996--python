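"""Window geometry, haplotype extraction, inheritance coding, OLS machinery,
scan behaviour and calibration statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import recqtl
from recqtl.errors import IdMismatchError, InvalidConfigError
from recqtl.hapscan import HaplotypeCall

from test_relatedness import panel_from_haplotypes


class TestEnumerateWindows:
    def test_hand_enumeration(self):
        windows = recqtl.enumerate_windows({"chr1": 110}, window_size=50, step=15)
        assert [w.start for w in windows] == [1, 16, 31, 46, 61]
        assert all(w.size == 50 for w in windows)

    def test_exact_fit_single_window(self):
        assert len(recqtl.enumerate_windows({"chr1": 50})) == 1

    def test_too_short_no_windows(self):
        assert recqtl.enumerate_windows({"chr1": 49}) == []

    @given(
        n=st.integers(1, 2000),
        size=st.integers(1, 100),
        step=st.integers(1, 60),
    )
    @settings(max_examples=100, deadline=None)
    def test_count_formula(self, n, size, step):
        windows = recqtl.enumerate_windows({"c": n}, size, step)
        expected = 0 if n < size else (n - size) // step + 1
        assert len(windows) == expected
        assert all(w.end <= n for w in windows)


class TestWindowHaplotypes:
    def _tiny_panel(self):
        # 4 individuals = 8 haplotypes over 2 SNPs: "00"x5, "01"x2, "10"x1
        haps = np.array(
            [
                [[0, 0], [0, 0]],
                [[0, 0], [0, 1]],
                [[0, 0], [0, 1]],
                [[0, 0], [1, 0]],
            ]
        )
        return panel_from_haplotypes(haps)

    def test_direct_counts(self):
        calls = recqtl.window_haplotypes(
            self._tiny_panel(), recqtl.Window("chr1", 1, 2), min_freq=0.01
        )
        freq = {c.alleles: c.frequency for c in calls}
        assert freq == {"00": 0.625, "01": 0.25, "10": 0.125}
        n_hom = {c.alleles: c.n_hom for c in calls}
        assert n_hom == {"00": 1, "01": 0, "10": 0}

    def test_min_freq_filter(self):
        calls = recqtl.window_haplotypes(
            self._tiny_panel(), recqtl.Window("chr1", 1, 2), min_freq=0.2
        )
        assert {c.alleles for c in calls} == {"00", "01"}

    def test_monomorphic_window(self):
        haps = np.zeros((6, 2, 3), dtype=np.uint8)
        calls = recqtl.window_haplotypes(
            panel_from_haplotypes(haps), recqtl.Window("chr1", 1, 3)
        )
        assert len(calls) == 1
        assert calls[0].frequency == 1.0
        assert calls[0].n_hom == 6

    def test_frequencies_sum_to_one(self, small_panel):
        window = recqtl.Window("chr1", 11, 40)
        calls = recqtl.window_haplotypes(small_panel, window, min_freq=0.0)
        assert sum(c.frequency for c in calls) == pytest.approx(1.0)


class TestHaplotypeDosage:
    def _panel(self):
        haps = np.array(
            [
                [[0, 1], [0, 1]],  # diplotype ("01", "01")
                [[0, 1], [0, 0]],  # ("01", "00")
                [[0, 0], [0, 0]],
                [[0, 1], [0, 1]],
            ]
        )
        return panel_from_haplotypes(haps)

    def _call(self, panel, n_hom=2, freq=0.5):
        return HaplotypeCall(panel.with_bp(recqtl.Window("chr1", 1, 2)), "01", freq, n_hom)

    def test_additive_and_recessive_coding(self):
        panel = self._panel()
        call = self._call(panel)
        add = recqtl.haplotype_dosage(panel, call, "additive")
        rec = recqtl.haplotype_dosage(panel, call, "recessive", min_hom_frac=0.0)
        assert list(add) == [2, 1, 0, 2]
        assert list(rec) == [1, 0, 0, 1]

    def test_recessive_ineligible_below_hom_fraction(self):
        # 3 homozygotes among 1000 individuals = 0.3% < 0.5%: skipped
        haps = np.zeros((1000, 2, 2), dtype=np.uint8)
        haps[:3, :, 1] = 1  # 3 individuals homozygous "01"
        haps[3:103, 0, 1] = 1  # 100 heterozygotes keep the haplotype common
        panel = panel_from_haplotypes(haps)
        call = self._call(panel, n_hom=3, freq=(6 + 100) / 2000)
        assert recqtl.haplotype_dosage(panel, call, "recessive") is None
        assert recqtl.haplotype_dosage(panel, call, "additive") is not None

    def test_additive_identity_with_recessive_and_het(self, small_panel):
        """additive = 2 * hom indicator + het indicator over random windows."""
        for start in (1, 31, 61):
            window = recqtl.Window("chr1", start, start + 29)
            for call in recqtl.window_haplotypes(small_panel, window):
                copies = small_panel.haplotype_copies(window, call.alleles)
                add = recqtl.haplotype_dosage(small_panel, call, "additive")
                assert np.array_equal(add, 2 * (copies == 2) + (copies == 1))

    def test_length_mismatch_errors(self):
        panel = self._panel()
        bad = HaplotypeCall(panel.with_bp(recqtl.Window("chr1", 1, 2)), "011", 0.5, 0)
        with pytest.raises(InvalidConfigError):
            recqtl.haplotype_dosage(panel, bad, "additive")


class TestFitAssociation:
    def test_hand_computed_slope(self):
        res = recqtl.fit_association(
            np.array([0, 1, 1, 2, 2, 3], dtype=float),
            np.array([0, 0, 1, 1, 2, 2], dtype=float),
        )
        assert res.beta == pytest.approx(1.0)

    def test_perfect_fit_no_crash(self):
        x = np.array([0.0, 1.0, 2.0, 0.0, 1.0])
        res = recqtl.fit_association(x.copy(), x)
        assert res.status == "perfect_fit"

    def test_constant_dosage_degenerate(self):
        res = recqtl.fit_association(np.arange(5.0), np.ones(5))
        assert res.status == "degenerate"
        assert np.isnan(res.p)

    def test_rank_deficient_covariates_error(self):
        y = np.arange(6.0)
        x = np.array([0, 1, 0, 1, 2, 2], dtype=float)
        cov = np.column_stack([np.ones(6), np.ones(6)])  # duplicates intercept
        with pytest.raises(InvalidConfigError):
            recqtl.fit_association(y, x, covariates=cov)

    def test_matches_pseudoinverse_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(15, 50))
            k = int(rng.integers(1, 4))
            cov = rng.normal(size=(n, k))
            x = rng.integers(0, 3, size=n).astype(float)
            if np.ptp(x) == 0:
                continue
            y = rng.normal(size=n)
            res = recqtl.fit_association(y, x, covariates=cov)
            design = np.column_stack([np.ones(n), cov, x])
            coef = np.linalg.pinv(design) @ y
            assert res.beta == pytest.approx(coef[-1], abs=1e-8)

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        n = 60
        cov = rng.normal(size=(n, 3))
        x = rng.integers(0, 3, size=n).astype(float)
        y = 0.3 * x + rng.normal(size=n)
        res = recqtl.fit_association(y, x, covariates=cov)
        fit = sm.OLS(y, np.column_stack([np.ones(n), cov, x])).fit()
        assert res.beta == pytest.approx(fit.params[-1], abs=1e-10)
        assert res.se == pytest.approx(fit.bse[-1], abs=1e-10)
        assert res.p == pytest.approx(fit.pvalues[-1], abs=1e-10)


class TestScan:
    def test_fast_path_matches_fit_association(self, qtl_sim):
        """Residualized scan statistics equal the full OLS fit."""
        panel, pcs = qtl_sim["panel"], qtl_sim["pcs"]
        y = qtl_sim["phenotypes"]
        result = recqtl.scan(panel, y, pcs=pcs, mode="recessive")
        r = result.top_hit()
        copies = panel.haplotype_copies(r.window, r.target)
        from recqtl.panel import aligned_phenotype

        full = recqtl.fit_association(
            aligned_phenotype(panel, y),
            (copies == 2).astype(float),
            covariates=pcs.vectors,
        )
        assert r.beta == pytest.approx(full.beta, abs=1e-10)
        assert r.se == pytest.approx(full.se, abs=1e-10)
        assert r.p == pytest.approx(full.p, rel=1e-8)

    def test_localizes_embedded_qtl(self, qtl_sim):
        result = recqtl.scan(
            qtl_sim["panel"], qtl_sim["phenotypes"], pcs=qtl_sim["pcs"],
            mode="recessive",
        )
        assert result.top_hit().window.overlaps(qtl_sim["causal"].window)

    def test_recessive_stronger_than_additive(self, qtl_sim):
        rec = recqtl.scan(
            qtl_sim["panel"], qtl_sim["phenotypes"], pcs=qtl_sim["pcs"],
            mode="recessive",
        )
        add = recqtl.scan(
            qtl_sim["panel"], qtl_sim["phenotypes"], pcs=qtl_sim["pcs"],
            mode="additive",
        )
        assert rec.top_hit().p < add.top_hit().p

    def test_conditional_scan_removes_signal(self, qtl_sim):
        """Conditioning on the causal recessive status extinguishes the QTL."""
        panel, causal = qtl_sim["panel"], qtl_sim["causal"]
        copies = panel.haplotype_copies(causal.window, causal.allele_string)
        rec_status = (copies == 2).astype(float)
        cond = recqtl.scan(
            panel, qtl_sim["phenotypes"], pcs=qtl_sim["pcs"],
            mode="recessive", conditional=rec_status,
        )
        causal_results = [
            r for r in cond.results if r.window.overlaps(causal.window)
        ]
        assert causal_results, "causal window still enumerated"
        assert min(r.p for r in causal_results) > cond.bonferroni()

    def test_permutation_invariance(self, small_panel, rng):
        y = rng.normal(size=small_panel.n_individuals)
        y[::7] -= 0.5
        ph = recqtl.make_phenotype_table(small_panel.ids, y)
        base = recqtl.scan(small_panel, ph, mode="additive")
        perm = rng.permutation(small_panel.n_individuals)
        shuffled = small_panel.reorder([small_panel.ids[i] for i in perm])
        permuted = recqtl.scan(shuffled, ph, mode="additive")
        assert base.n_tests == permuted.n_tests
        a = {(r.window.chrom, r.window.start, r.target): r.p for r in base.results}
        b = {(r.window.chrom, r.window.start, r.target): r.p for r in permuted.results}
        assert a.keys() == b.keys()
        for key in a:
            assert a[key] == pytest.approx(b[key], rel=1e-9)

    def test_id_mismatch_errors(self, small_panel):
        ph = recqtl.make_phenotype_table(["nobody"], np.array([1.0]))
        with pytest.raises(IdMismatchError):
            recqtl.scan(small_panel, ph)

    def test_deterministic_ordering(self, qtl_sim):
        result = recqtl.scan(
            qtl_sim["panel"], qtl_sim["phenotypes"], mode="additive"
        )
        keys = [
            (r.window.chrom, r.window.start, -r.frequency, r.target)
            for r in result.results
        ]
        assert keys == sorted(keys)


class TestThresholdsAndLambda:
    def test_bonferroni_values(self):
        assert recqtl.bonferroni_threshold(10) == pytest.approx(0.005)
        assert recqtl.bonferroni_threshold(186_278) == pytest.approx(2.68e-7, rel=5e-3)
        assert recqtl.bonferroni_threshold(12_861_528) == pytest.approx(3.888e-9, rel=1e-3)
        with pytest.raises(InvalidConfigError):
            recqtl.bonferroni_threshold(0)

    def test_lambda_exact_at_half(self):
        assert recqtl.genomic_lambda(np.full(100, 0.5)) == pytest.approx(1.0)

    def test_lambda_uniform_null(self, rng):
        p = rng.uniform(size=10_000)
        assert 0.95 <= recqtl.genomic_lambda(p) <= 1.05

    def test_lambda_inflated_when_p_halved(self, rng):
        p = rng.uniform(size=10_000)
        assert recqtl.genomic_lambda(p / 2) > recqtl.genomic_lambda(p)

    def test_lambda_input_validation(self):
        with pytest.raises(InvalidConfigError):
            recqtl.genomic_lambda(np.array([]))
        with pytest.raises(InvalidConfigError):
            recqtl.genomic_lambda(np.array([0.0, 0.5]))
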