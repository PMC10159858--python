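"""Statistical tests against exhaustive oracles; the screen's mechanics."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import fisher_exact as scipy_fisher_2x2

from bloodsift.assoc import (
    bh_adjust,
    derive_phenotypes,
    fisher_exact_2xk,
    run_association_screen,
    test_categorical as categorical_test,
    test_continuous as continuous_test,
)
from bloodsift.errors import DataError
from bloodsift.synth import simulate_phenotypes
from conftest import presence_frame


def fisher_brute_force(table: np.ndarray) -> float:
    """Enumerate every table with the observed margins; two-sided p sums
    the probabilities of tables no more probable than the observed."""
    table = np.asarray(table, dtype=int)
    cols = table.sum(axis=0)
    m = int(table[0].sum())

    def prob(top):
        num = math.prod(math.comb(int(n), int(a)) for n, a in zip(cols, top))
        return num / math.comb(int(cols.sum()), m)

    tops = [t for t in itertools.product(*(range(c + 1) for c in cols))
            if sum(t) == m]
    p_obs = prob(table[0])
    return sum(prob(t) for t in tops if prob(t) <= p_obs * (1 + 1e-9))


def mwu_brute_force(x, y) -> tuple[float, float]:
    """Enumerate all group labelings; two-sided p counts labelings whose
    U deviates from n1*n2/2 at least as much as observed (mid-ranks)."""
    from scipy.stats import rankdata
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = rankdata(pooled)
    mu = n1 * (len(pooled) - n1) / 2.0
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    dev = abs(u_obs - mu)
    hits = total = 0
    for comb in itertools.combinations(range(len(pooled)), n1):
        u = ranks[list(comb)].sum() - n1 * (n1 + 1) / 2.0
        total += 1
        if abs(u - mu) >= dev - 1e-9:
            hits += 1
    return u_obs, hits / total


class TestFisherExact:
    def test_perfect_separation_2x2(self):
        # 2 / C(20, 10) tables are at least as extreme
        p = fisher_exact_2xk(np.array([[10, 0], [0, 10]]))
        assert p == pytest.approx(2 / 184756)

    def test_balanced_table_p_one(self):
        assert fisher_exact_2xk(np.array([[5, 5], [5, 5]])) == pytest.approx(1.0)

    @pytest.mark.parametrize("table", [
        [[3, 1], [1, 3]], [[2, 0, 1], [1, 2, 1]], [[4, 0], [0, 4]],
        [[1, 2, 1], [2, 0, 2]], [[0, 3], [3, 2]], [[2, 2, 2], [1, 0, 1]],
    ])
    def test_matches_brute_force_enumeration(self, table):
        table = np.array(table)
        assert fisher_exact_2xk(table) == pytest.approx(
            fisher_brute_force(table), abs=1e-12)

    def test_matches_scipy_on_2x2(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            table = rng.integers(0, 30, size=(2, 2))
            if table.sum() == 0 or table.sum(axis=0).min() == table.sum():
                continue
            assert fisher_exact_2xk(table) == pytest.approx(
                scipy_fisher_2x2(table)[1], rel=1e-9)

    def test_monte_carlo_close_to_exact(self):
        table = np.array([[8, 3, 9], [12, 17, 11]])
        exact = fisher_exact_2xk(table)
        mc = fisher_exact_2xk(table, max_tables=1, n_mc=100_000, seed=0)
        assert mc == pytest.approx(exact, abs=0.01)

    def test_categorical_wrapper_excludes_missing(self):
        pres = [True, True, False, False, True, False]
        cat = ["a", "b", "a", "b", None, None]
        _, p = categorical_test(pres, cat)
        assert p == pytest.approx(
            fisher_brute_force(np.array([[1, 1], [1, 1]])))

    def test_single_category_after_missing_is_error(self):
        with pytest.raises(DataError, match="categories"):
            categorical_test([True, False], ["a", None])


class TestMannWhitney:
    def test_full_separation_example(self):
        u, p = continuous_test([1, 1, 1, 0, 0, 0], [1, 2, 3, 4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)       # 2 of C(6,3)=20 labelings

    def test_identical_groups_p_one(self):
        _, p = continuous_test([1, 0, 1, 0], [3.0, 3.0, 7.0, 7.0])
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_enumeration_small_n(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        n1 = int(rng.integers(1, n))
        vals = rng.integers(0, 5, size=n).astype(float)   # ties likely
        pres = np.zeros(n, dtype=bool)
        pres[:n1] = True
        u_mine, p_mine = continuous_test(pres, vals)
        u_oracle, p_oracle = mwu_brute_force(vals[:n1], vals[n1:])
        assert u_mine == pytest.approx(u_oracle)
        assert p_mine == pytest.approx(p_oracle, abs=1e-12)

    def test_large_n_uses_normal_approximation(self):
        rng = np.random.default_rng(1)
        pres = np.concatenate([np.ones(40, bool), np.zeros(40, bool)])
        vals = rng.normal(size=80)
        _, p = continuous_test(pres, vals)
        assert 0.0 <= p <= 1.0

    def test_missing_values_excluded(self):
        pres = [1, 1, 1, 0, 0, 0, 1]
        vals = [1, 2, 3, 4, 5, 6, np.nan]
        _, p = continuous_test(pres, vals)
        assert p == pytest.approx(0.1)

    def test_empty_group_is_error(self):
        with pytest.raises(DataError, match="empty"):
            continuous_test([1, 1], [2.0, 3.0])

    def test_type_one_error_calibrated(self):
        """Asymptotic two-sided MWU rejects ~5% under the null."""
        rng = np.random.default_rng(0)
        rejections = 0
        n_rep = 400
        for _ in range(n_rep):
            pres = np.zeros(80, bool)
            pres[:30] = True
            vals = rng.normal(size=80)
            _, p = continuous_test(pres, vals)
            rejections += p < 0.05
        assert abs(rejections / n_rep - 0.05) < 0.03


class TestBhAdjust:
    def test_step_up_examples(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])
        assert bh_adjust([0.04, 1.0]) == pytest.approx([0.08, 1.0])
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    def test_matches_step_up_formula_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            p = rng.random(25)
            adj = bh_adjust(p)
            order = np.argsort(p)
            m = len(p)
            stepped = p[order] * m / np.arange(1, m + 1)
            stepped = np.minimum.accumulate(stepped[::-1])[::-1]
            expected = np.empty(m)
            expected[order] = np.minimum(stepped, 1.0)
            assert adj == pytest.approx(expected)

    def test_permutation_equivariance_and_bounds(self):
        rng = np.random.default_rng(1)
        p = rng.random(15)
        perm = rng.permutation(15)
        assert bh_adjust(p)[perm] == pytest.approx(bh_adjust(p[perm]))
        assert bh_adjust(p).max() <= 1.0
        assert np.all(bh_adjust(p) >= p)

    def test_out_of_range_rejected(self):
        with pytest.raises(DataError):
            bh_adjust([0.5, 1.5])


class TestDerivePhenotypes:
    def test_threshold_boundaries(self):
        pheno = pd.DataFrame({
            "age": [65, 64.9], "bmi": [30.0, 30.1], "tg": [2.3, 2.4],
            "tc": [6.3, 6.2], "sbp": [135, 130], "dbp": [75, 80],
        })
        d = derive_phenotypes(pheno)
        assert d["elderly"].tolist() == [True, False]      # age >= 65
        assert d["obese"].tolist() == [False, True]        # strictly > 30
        assert d["high_tg"].tolist() == [False, True]      # strictly > 2.3
        assert d["high_tc"].tolist() == [True, False]      # >= 6.3
        assert d["high_bp"].tolist() == [False, True]      # conjunction

    def test_missing_propagates(self):
        pheno = pd.DataFrame({"age": [70.0, np.nan]})
        d = derive_phenotypes(pheno)
        assert d["elderly"][0] is np.True_ or d["elderly"][0] == True  # noqa: E712
        assert pd.isna(d["elderly"][1])


class TestScreen:
    @staticmethod
    def _data(n=300, n_species=3, prevalence=0.4, seed=0):
        rng = np.random.default_rng(seed)
        present = presence_frame(
            rng.random((n, n_species)) < prevalence,
            samples=[f"S{i:04d}" for i in range(n)],
            species=[f"sp{j}" for j in range(n_species)])
        meta = pd.DataFrame({"cohort": ["c1"] * (n // 2) + ["c2"] * (n - n // 2)},
                            index=present.index)
        pheno = simulate_phenotypes(meta, seed=seed + 1)
        return present, pheno

    def test_min_present_boundary_skipped_with_reason(self):
        present, pheno = self._data()
        rare = np.zeros(len(present), dtype=bool)
        rare[:49] = True                          # 49 < 50: skipped
        present["rare_sp"] = rare
        measured, _, skips = run_association_screen(present, pheno, seed=0)
        assert "rare_sp" not in set(measured["species"])
        reasons = {s["species"]: s["reason"] for s in skips}
        assert "49" in reasons["rare_sp"]

    def test_families_and_bh_within_family(self):
        present, pheno = self._data()
        measured, derived, _ = run_association_screen(present, pheno, seed=0)
        # 2 cohorts x 3 species x (2 categorical + 6 continuous)
        assert len(measured) == 2 * 3 * 8
        assert len(derived) == 2 * 3 * 5
        assert measured["p_adjusted"].to_numpy() == pytest.approx(
            bh_adjust(measured["p"]))
        assert derived["p_adjusted"].to_numpy() == pytest.approx(
            bh_adjust(derived["p"]))
        assert set(measured.loc[measured.test == "fisher", "phenotype"]) <= {
            "sex", "ancestry"}
        assert measured.loc[measured.test == "fisher", "statistic"].isna().all()

    def test_deterministic_given_seed(self):
        present, pheno = self._data()
        m1, d1, _ = run_association_screen(present, pheno, seed=11)
        m2, d2, _ = run_association_screen(present, pheno, seed=11)
        pd.testing.assert_frame_equal(m1, m2)
        pd.testing.assert_frame_equal(d1, d2)
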