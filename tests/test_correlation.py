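"""Spearman correlation, BH adjustment, family running, significance filter."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from apokat.correlation import (
    PAN_CANCER,
    CorrelationResult,
    UntestablePair,
    bh_adjust,
    run_family,
    significant,
    spearman,
)
from apokat.correlation import TestFamily as Family  # avoid pytest collection


class TestSpearman:
    def test_perfect_monotone(self):
        rho, p = spearman([1, 2, 3, 4], [10, 20, 30, 40])
        assert rho == 1.0
        assert p == pytest.approx(2.0 / math.factorial(4))

    def test_perfect_antitone(self):
        rho, _ = spearman([1, 2, 3, 4], [8, 6, 4, 2])
        assert rho == -1.0

    def test_hand_computed_n3(self):
        rho, _ = spearman([1, 2, 3], [2, 1, 3])
        assert rho == pytest.approx(0.5)

    def test_incomplete_pairs_dropped(self):
        rho, _ = spearman([1, 2, 3, 4, np.nan], [10, 20, 30, np.nan, 50])
        assert rho == 1.0  # computed on the 3 complete pairs

    def test_too_few_pairs_untestable(self):
        with pytest.raises(UntestablePair):
            spearman([1, 2], [3, 4])

    def test_zero_rank_variance_untestable(self):
        with pytest.raises(UntestablePair):
            spearman([5, 5, 5, 5], [1, 2, 3, 4])

    def test_matches_scipy_on_random_inputs(self, rng):
        for _ in range(300):
            n = int(rng.integers(5, 60))
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            rho, p = spearman(x, y)
            ref = stats.spearmanr(x, y)
            assert rho == pytest.approx(ref.statistic, abs=1e-12)
            assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_ties_use_average_ranks(self, rng):
        x = np.array([1.0, 1.0, 2.0, 3.0, 3.0, 4.0])
        y = rng.normal(size=6)
        rho, _ = spearman(x, y)
        assert rho == pytest.approx(stats.spearmanr(x, y).statistic, abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        rho1, _ = spearman(x, y)
        rho2, _ = spearman(np.exp(x), y**3)
        assert rho1 == pytest.approx(rho2, abs=1e-12)

    def test_antisymmetric_under_reversal(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        rho1, _ = spearman(x, y)
        rho2, _ = spearman(x, -y)
        assert rho1 == pytest.approx(-rho2, abs=1e-12)


class TestBHAdjust:
    def test_hand_example_two(self):
        assert bh_adjust([0.01, 0.04]).tolist() == pytest.approx([0.02, 0.04])

    def test_hand_example_three(self):
        assert bh_adjust([0.03, 0.01, 0.02]).tolist() == pytest.approx(
            [0.03, 0.03, 0.03]
        )

    def test_single_p_identity(self):
        assert bh_adjust([0.5]).tolist() == [0.5]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_matches_statsmodels_on_random_vectors(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(300):
            m = int(rng.integers(1, 200))
            p = rng.uniform(size=m)
            ours = bh_adjust(p)
            _, ref, _, _ = multipletests(p, method="fdr_bh")
            assert np.max(np.abs(ours - ref)) < 1e-12

    def test_monotone_with_raw_p_order(self, rng):
        p = rng.uniform(size=100)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()


def _tables(n, seed=0, rho_latent=None):
    rng = np.random.default_rng(seed)
    cells = [f"CL{i}" for i in range(n)]
    x = rng.normal(size=n)
    if rho_latent is None:
        y = rng.normal(size=n)
    else:
        y = rho_latent * x + math.sqrt(1 - rho_latent**2) * rng.normal(size=n)
    left = pd.DataFrame({"gene": x}, index=cells)
    right = pd.DataFrame({"drug": y}, index=cells)
    return left, right


class TestRunFamily:
    def test_single_test_family_padj_equals_p(self):
        left, right = _tables(20, rho_latent=0.99)
        fam = Family("f", ["gene"], ["drug"])
        (res,) = run_family(fam, left, right)
        assert res.p_adj == res.p and res.n_tests == 1

    def test_stratum_below_min_n_omitted(self):
        left, right = _tables(9)
        cat = {f"CL{i}": ("A" if i < 4 else "B") for i in range(9)}
        fam = Family("f", ["gene"], ["drug"], strata=["A", "B"], min_n=5)
        results = run_family(fam, left, right, cat)
        assert {r.stratum for r in results} == {"B"}

    def test_pairwise_complete_n_counted_per_pair(self):
        left, right = _tables(10)
        left.iloc[:6, 0] = np.nan  # only 4 complete pairs remain
        fam = Family("f", ["gene"], ["drug"], min_n=5)
        assert run_family(fam, left, right) == []

    def test_null_pvalues_uniform_consistent(self):
        # pooled raw p over independent null tests should pass a KS test
        pvals = []
        for seed in range(100):
            left, right = _tables(25, seed=seed)
            fam = Family("f", ["gene"], ["drug"])
            (res,) = run_family(fam, left, right)
            pvals.append(res.p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_unresolvable_variable_is_error(self):
        left, right = _tables(10)
        with pytest.raises(KeyError):
            run_family(Family("f", ["nope"], ["drug"]), left, right)

    def test_family_size_reported_on_every_result(self):
        rng = np.random.default_rng(5)
        cells = [f"CL{i}" for i in range(12)]
        left = pd.DataFrame(rng.normal(size=(12, 2)), index=cells, columns=["g1", "g2"])
        right = pd.DataFrame(rng.normal(size=(12, 3)), index=cells, columns=list("abc"))
        results = run_family(Family("f", ["g1", "g2"], list("abc")), left, right)
        assert len(results) == 6
        assert all(r.n_tests == 6 for r in results)
        expected = bh_adjust([r.p for r in results])
        assert [r.p_adj for r in results] == pytest.approx(expected.tolist())


class TestSignificant:
    def make(self, rho, p_adj):
        return CorrelationResult(
            left="g", right="d", stratum=PAN_CANCER, n=10, rho=rho, p=p_adj / 2,
            p_adj=p_adj, family_id="f", n_tests=1,
        )

    def test_kept_and_dropped(self):
        kept = self.make(0.9, 0.01)
        weak_rho = self.make(0.2, 0.001)
        boundary_p = self.make(0.9, 0.05)
        out = significant([kept, weak_rho, boundary_p])
        assert out == [kept]

    def test_boundary_rho_dropped(self):
        assert significant([self.make(0.25, 0.01)]) == []

    def test_sorted_by_padj_then_abs_rho(self):
        a = self.make(0.5, 0.02)
        b = self.make(-0.9, 0.02)
        c = self.make(0.3, 0.001)
        assert significant([a, b, c]) == [c, b, a]

    def test_unadjusted_results_rejected(self):
        res = CorrelationResult(
            left="g", right="d", stratum=PAN_CANCER, n=10, rho=0.9, p=0.001,
        )
        with pytest.raises(ValueError):
            significant([res])
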