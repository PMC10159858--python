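"""Host-phenotype association screening for species presence.

Each cohort is screened separately: categorical phenotypes (sex,
ancestry) against species presence with a two-sided Fisher's exact test
on the 2 x k contingency table, continuous phenotypes (age, BMI, total
cholesterol, triglycerides, systolic/diastolic blood pressure) with a
two-sided Mann-Whitney U test comparing carriers against non-carriers.
Benjamini-Hochberg correction is applied once over the pooled p-values
from both tests and all cohorts; derived dichotomous phenotypes
(elderly, obese, high TG/TC/BP) form a second, separately corrected
family.  Species present in fewer than 50 samples overall are skipped,
as are tests degenerate after missing-data removal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata
from statsmodels.stats.multitest import multipletests

from .errors import DataError

CATEGORICAL_PHENOTYPES = ("sex", "ancestry")
CONTINUOUS_PHENOTYPES = ("age", "bmi", "tc", "tg", "sbp", "dbp")
DERIVED_PHENOTYPES = ("elderly", "obese", "high_tg", "high_tc", "high_bp")
MIN_PRESENT = 50

# dichotomisation thresholds for the derived phenotypes
ELDERLY_AGE = 65.0        # age >= 65
OBESE_BMI = 30.0          # BMI strictly > 30 kg/m^2
HIGH_TG = 2.3             # triglycerides strictly > 2.3 mmol/l
HIGH_TC = 6.3             # total cholesterol >= 6.3 mmol/l
HIGH_SBP = 130.0          # systolic >= 130 mmHg, jointly with
HIGH_DBP = 80.0           # diastolic >= 80 mmHg


# ------------------------------------------------ Fisher's exact (2 x k)

def _log_comb(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def _table_logp(top: tuple[int, ...], cols: tuple[int, ...], m: int, n: int) -> float:
    """Log multivariate-hypergeometric probability of the top row."""
    lp = -_log_comb(n, m)
    for a, nj in zip(top, cols):
        lp += _log_comb(nj, a)
    return lp


def _enumerate_tables(cols: tuple[int, ...], m: int):
    """All top rows (a_1..a_k) with sum m and 0 <= a_j <= col margin."""
    k = len(cols)

    def rec(j: int, remaining: int, prefix: tuple[int, ...]):
        if j == k - 1:
            if 0 <= remaining <= cols[j]:
                yield prefix + (remaining,)
            return
        tail_cap = sum(cols[j + 1:])
        lo = max(0, remaining - tail_cap)
        hi = min(cols[j], remaining)
        for a in range(lo, hi + 1):
            yield from rec(j + 1, remaining - a, prefix + (a,))

    yield from rec(0, m, ())


def _count_tables(cols: tuple[int, ...], m: int) -> int:
    """Number of feasible top rows (DP, cheap)."""
    counts = {0: 1}
    for nj in cols:
        new: dict[int, int] = {}
        for s, c in counts.items():
            for a in range(0, min(nj, m - s) + 1):
                new[s + a] = new.get(s + a, 0) + c
        counts = new
    return counts.get(m, 0)


def fisher_exact_2xk(
    table: np.ndarray,
    max_tables: int = 20_000,
    n_mc: int = 20_000,
    seed: int | None = None,
) -> float:
    """Two-sided Fisher's exact p for a 2 x k presence-by-category table.

    Small tables are evaluated by full enumeration over all tables with
    the observed margins (two-sided p sums the probabilities of tables
    no more likely than the observed one, the fisher.test convention);
    large tables fall back to a seeded multivariate-hypergeometric Monte
    Carlo estimate of the same quantity.
    """
    table = np.asarray(table, dtype=np.int64)
    if table.shape[0] != 2 or table.shape[1] < 2:
        raise DataError("fisher_exact_2xk expects a 2 x k table, k >= 2")
    if (table < 0).any():
        raise DataError("negative cell counts")
    cols = tuple(int(x) for x in table.sum(axis=0))
    m = int(table[0].sum())
    n = int(table.sum())
    if n == 0 or m == 0 or m == n or min(cols) == n:
        return 1.0
    from scipy.special import gammaln

    cols_arr = np.asarray(cols, dtype=float)

    def _logp_rows(tops: np.ndarray) -> np.ndarray:
        return (
            gammaln(cols_arr + 1.0)[None, :]
            - gammaln(tops + 1.0)
            - gammaln(cols_arr[None, :] - tops + 1.0)
        ).sum(axis=1) - _log_comb(n, m)

    obs_lp = float(_logp_rows(table[0][None, :].astype(float))[0])
    cutoff = obs_lp + 1e-7
    if len(cols) == 2:
        # 2x2: one free cell, enumerate its whole range vectorised
        a = np.arange(max(0, m - cols[1]), min(cols[0], m) + 1, dtype=float)
        tops = np.column_stack([a, m - a])
        lps = _logp_rows(tops)
        return float(min(np.exp(lps[lps <= cutoff]).sum(), 1.0))
    if _count_tables(cols, m) <= max_tables:
        tops = np.array(list(_enumerate_tables(cols, m)), dtype=float)
        lps = _logp_rows(tops)
        total = float(np.exp(lps[lps <= cutoff]).sum())
        return float(min(total, 1.0))
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_hypergeometric(cols, m, size=n_mc)
    lps = _logp_rows(draws.astype(float))
    return float(np.mean(lps <= cutoff))


def test_categorical(
    presence_vector,
    category_vector,
    seed: int | None = None,
) -> tuple[None, float]:
    """Fisher's exact test of presence prevalence across categories.

    Missing phenotype values are excluded first; a single remaining
    category is an error (callers treat it as a skip).  No statistic is
    reported for Fisher's test (matching the convention of leaving the
    statistic blank), only the two-sided p.
    """
    pres = pd.Series(np.asarray(presence_vector, dtype=object)).astype(bool)
    cat = pd.Series(np.asarray(category_vector, dtype=object))
    keep = cat.notna().to_numpy()
    pres, cat = pres[keep], cat[keep]
    levels = pd.unique(cat)
    if len(levels) < 2:
        raise DataError("fewer than 2 non-empty categories after missing-data removal")
    table = np.vstack([
        [(pres & (cat == lv).to_numpy()).sum() for lv in levels],
        [(~pres & (cat == lv).to_numpy()).sum() for lv in levels],
    ])
    return None, fisher_exact_2xk(table, seed=seed)


# ------------------------------------------------ Mann-Whitney U

def _mwu_exact_two_sided(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney via rank-sum distribution (ties ok).

    Counts, over all C(n, n1) group labelings of the observed values,
    the labelings whose U deviates from its null mean n1*n2/2 at least
    as much as the observed one (the permutation distribution of U is
    symmetric about that mean, so this matches doubling the smaller
    tail).  Mid-ranks are used throughout; doubled ranks keep the
    dynamic program integral.
    """
    n1, n2 = len(x), len(y)
    combined = np.concatenate([x, y])
    scores = np.round(2.0 * rankdata(combined)).astype(np.int64)
    u_obs = float(rankdata(combined)[:n1].sum()) - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    dev = abs(u_obs - mu)
    max_s = int(scores.sum())
    # dp[k][s] = number of size-k subsets with doubled-rank sum s
    dp = np.zeros((n1 + 1, max_s + 1), dtype=np.float64)
    dp[0, 0] = 1.0
    for sc in scores:
        # snapshot before adding: each value may be used at most once
        dp[1:, sc:] += dp[:-1, :max_s + 1 - sc].copy()
    counts = dp[n1]
    s_vals = np.arange(max_s + 1)
    u_vals = s_vals / 2.0 - n1 * (n1 + 1) / 2.0
    extreme = np.abs(u_vals - mu) >= dev - 1e-9
    total = counts.sum()
    p = float(counts[extreme].sum() / total)
    return u_obs, min(p, 1.0)


def test_continuous(presence_vector, values) -> tuple[float, float]:
    """Two-sided Mann-Whitney U comparing a phenotype by species presence.

    Missing values are excluded; both groups must be non-empty.  Groups
    both smaller than 20 use the exact tie-aware permutation
    distribution; otherwise the tie-corrected normal approximation with
    continuity correction.  Returns (U for the present group, p).
    """
    pres = pd.Series(np.asarray(presence_vector, dtype=object)).astype(bool).to_numpy()
    vals = pd.to_numeric(pd.Series(values), errors="coerce").to_numpy(dtype=float)
    keep = ~np.isnan(vals)
    pres, vals = pres[keep], vals[keep]
    x, y = vals[pres], vals[~pres]
    if len(x) == 0 or len(y) == 0:
        raise DataError("one presence group is empty")
    if max(len(x), len(y)) < 20:
        return _mwu_exact_two_sided(x, y)
    res = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                       use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order kept)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise DataError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ------------------------------------------------ derived phenotypes

def derive_phenotypes(pheno: pd.DataFrame) -> pd.DataFrame:
    """Dichotomise age/BMI/lipid/blood-pressure columns.

    elderly = age >= 65; obese = BMI > 30; high_tg = TG > 2.3 mmol/l;
    high_tc = TC >= 6.3 mmol/l; high_bp = SBP >= 130 AND DBP >= 80.
    Missing inputs propagate to missing outputs (nullable booleans).
    """
    out = pd.DataFrame(index=pheno.index)
    def col(name):
        return pd.to_numeric(pheno[name], errors="coerce") if name in pheno else None
    age, bmi, tg, tc = col("age"), col("bmi"), col("tg"), col("tc")
    sbp, dbp = col("sbp"), col("dbp")
    if age is not None:
        out["elderly"] = (age >= ELDERLY_AGE).mask(age.isna()).astype("boolean")
    if bmi is not None:
        out["obese"] = (bmi > OBESE_BMI).mask(bmi.isna()).astype("boolean")
    if tg is not None:
        out["high_tg"] = (tg > HIGH_TG).mask(tg.isna()).astype("boolean")
    if tc is not None:
        out["high_tc"] = (tc >= HIGH_TC).mask(tc.isna()).astype("boolean")
    if sbp is not None and dbp is not None:
        hb = (sbp >= HIGH_SBP) & (dbp >= HIGH_DBP)
        out["high_bp"] = hb.mask(sbp.isna() | dbp.isna()).astype("boolean")
    return out


# ------------------------------------------------ the screen

@dataclass
class AssociationResult:
    species: str
    phenotype: str
    cohort: str
    test: str                      # "fisher" or "mann_whitney"
    statistic: float | None
    p: float
    p_adjusted: float | None = None
    n_present: int = 0
    n_absent: int = 0
    n_cohorts_replicated: int | None = None


def run_association_screen(
    present: pd.DataFrame,
    pheno: pd.DataFrame,
    min_present: int = MIN_PRESENT,
    alpha: float = 0.05,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, list[dict]]:
    """Screen every cohort x species x phenotype combination.

    *pheno* is indexed by sample_id and must carry a ``cohort`` column;
    species present in fewer than *min_present* samples overall are
    skipped.  BH correction is applied once across the pooled measured-
    phenotype family (Fisher + Mann-Whitney, all cohorts) and once
    across the derived-phenotype family.  Significant hits are annotated
    with the number of cohorts in which the same (species, phenotype)
    pair is significant.  Returns (measured results, derived results,
    skip log).
    """
    if "cohort" not in pheno.columns:
        raise DataError("phenotype table must contain a 'cohort' column")
    common = present.index.intersection(pheno.index)
    present = present.loc[common]
    pheno = pheno.loc[common]
    totals = present.sum(axis=0)
    tested_species = totals.index[totals >= min_present].tolist()
    skips: list[dict] = [
        {"species": sp, "reason": f"present in {int(totals[sp])} < {min_present} samples"}
        for sp in totals.index[totals < min_present]
    ]
    derived = derive_phenotypes(pheno)
    categorical = [c for c in CATEGORICAL_PHENOTYPES if c in pheno.columns]
    continuous = [c for c in CONTINUOUS_PHENOTYPES if c in pheno.columns]
    rng = np.random.default_rng(seed)
    measured: list[AssociationResult] = []
    derived_res: list[AssociationResult] = []
    for cohort, sub_pheno in pheno.groupby("cohort", observed=True, sort=True):
        sub_present = present.loc[sub_pheno.index]
        sub_derived = derived.loc[sub_pheno.index]
        for sp in tested_species:
            vec = sub_present[sp].to_numpy()
            n_pres, n_abs = int(vec.sum()), int(len(vec) - vec.sum())
            for ph in categorical:
                cat = sub_pheno[ph].where(sub_pheno[ph].notna() & (sub_pheno[ph] != ""))
                try:
                    _, p = test_categorical(
                        vec, cat, seed=int(rng.integers(2 ** 31))
                    )
                except DataError as exc:
                    skips.append({"species": sp, "phenotype": ph,
                                  "cohort": str(cohort), "reason": str(exc)})
                    continue
                measured.append(AssociationResult(
                    sp, ph, str(cohort), "fisher", None, p,
                    n_present=n_pres, n_absent=n_abs))
            for ph in continuous:
                try:
                    u, p = test_continuous(vec, sub_pheno[ph])
                except DataError as exc:
                    skips.append({"species": sp, "phenotype": ph,
                                  "cohort": str(cohort), "reason": str(exc)})
                    continue
                measured.append(AssociationResult(
                    sp, ph, str(cohort), "mann_whitney", u, p,
                    n_present=n_pres, n_absent=n_abs))
            for ph in sub_derived.columns:
                flag = sub_derived[ph]
                try:
                    _, p = test_categorical(
                        vec, flag.astype(object).where(flag.notna()),
                        seed=int(rng.integers(2 ** 31)),
                    )
                except DataError as exc:
                    skips.append({"species": sp, "phenotype": ph,
                                  "cohort": str(cohort), "reason": str(exc)})
                    continue
                derived_res.append(AssociationResult(
                    sp, ph, str(cohort), "fisher", None, p,
                    n_present=n_pres, n_absent=n_abs))

    def finalise(results: list[AssociationResult]) -> pd.DataFrame:
        if not results:
            return pd.DataFrame(columns=[
                "species", "phenotype", "cohort", "test", "statistic", "p",
                "p_adjusted", "n_present", "n_absent", "n_cohorts_replicated"])
        adj = bh_adjust([r.p for r in results])
        for r, a in zip(results, adj):
            r.p_adjusted = float(a)
        sig = [(r.species, r.phenotype) for r in results if r.p_adjusted < alpha]
        from collections import Counter
        reps = Counter(sig)
        for r in results:
            if r.p_adjusted < alpha:
                r.n_cohorts_replicated = reps[(r.species, r.phenotype)]
        return pd.DataFrame([r.__dict__ for r in results])

    return finalise(measured), finalise(derived_res), skips
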