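"""Synthetic low-biomass metagenome generator with planted ground truth.

Every pipeline stage is benchmarked against data whose answer is known:

* a multi-cohort count matrix in which *contaminant* species are highly
  prevalent in a home laboratory batch (and correlated there through a
  shared per-sample latent factor, the within-batch kitome signature),
  *genuine* species occur sporadically at low population prevalence
  independent of batch, and a broad tail of *noise* species receives a
  few misclassified reads per sample;
* host phenotypes with optional planted presence-phenotype effects;
* circular-genome coverage tracks with a planted peak-to-trough ratio
  and Poisson sampling noise, plus genome sequences whose GC skew
  switches sign at the planted origin and terminus.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit, logit, ndtri
from scipy.stats import truncnorm

from .errors import DataError
from .replication import CoverageTrack


@dataclass
class SimulationConfig:
    """Study conditions for the cohort count-matrix generator.

    Defaults emulate a multi-cohort adult population processed in
    laboratory batches: per-sample microbial read totals lognormal with
    median ~6,000 read pairs, genuine taxa at <= 5% prevalence, batch
    contaminants at 40% prevalence in their home batch versus 5%
    elsewhere, and within-batch contaminant co-occurrence driven by a
    Gaussian copula with correlation 0.8.
    """

    n_samples: int = 2000
    n_cohorts: int = 4
    batch_variables: dict[str, int] = field(
        default_factory=lambda: {
            "extraction_kit": 4, "library_kit": 4, "sbs_lot": 4, "flow_cell": 4,
        }
    )
    assignment: str = "blocks"              # "blocks" | "independent"
    n_genuine_species: int = 20
    genuine_prevalence_range: tuple[float, float] = (0.001, 0.05)
    genuine_ra_range: tuple[float, float] = (0.01, 0.3)
    n_contaminant_species: int = 30
    contaminant_home_prevalence: float = 0.4
    contaminant_background_prevalence: float = 0.05
    contaminant_ra_range: tuple[float, float] = (0.01, 0.3)
    within_batch_correlation: float = 0.8
    total_reads_median: float = 6000.0
    total_reads_sigma: float = 1.0
    n_noise_species: int = 1500
    noise_max_reads: int = 10
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 1 or self.n_cohorts < 1:
            raise DataError("sample and cohort counts must be positive")
        for lo, hi, name in (
            (*self.genuine_prevalence_range, "genuine_prevalence_range"),
        ):
            if not (0 <= lo <= hi <= 1):
                raise DataError(f"{name} must lie in [0, 1]")
        for p, name in (
            (self.contaminant_home_prevalence, "contaminant_home_prevalence"),
            (self.contaminant_background_prevalence,
             "contaminant_background_prevalence"),
        ):
            if not (0 <= p <= 1):
                raise DataError(f"{name} must lie in [0, 1]")
        if not (0 <= self.within_batch_correlation < 1):
            raise DataError("within_batch_correlation must lie in [0, 1)")
        if self.n_samples < self.n_cohorts:
            raise DataError("fewer samples than cohorts")


@dataclass
class PlantedEffect:
    """Presence of *species* shifts the odds of a derived condition.

    Conditions: ``elderly`` (age >= 65), ``obese`` (BMI > 30),
    ``high_tg`` (TG > 2.3), ``high_tc`` (TC >= 6.3).  ``log_odds`` is
    the shift applied to carriers.
    """

    species: str
    condition: str
    log_odds: float


@dataclass
class SyntheticTruth:
    """Planted ground truth for recovery tests."""

    contaminants: dict[str, tuple[str, str]] = field(default_factory=dict)
    genuine: dict[str, float] = field(default_factory=dict)
    noise_species: list[str] = field(default_factory=list)
    phenotype_effects: list[PlantedEffect] = field(default_factory=list)
    ptr: dict[str, float] = field(default_factory=dict)
    ori: dict[str, float] = field(default_factory=dict)
    ter: dict[str, float] = field(default_factory=dict)
    skew_switches: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = set(self.contaminants) & set(self.genuine)
        if overlap:
            raise DataError(f"truth species sets overlap: {sorted(overlap)[:5]}")

    def to_json(self, path: str | None = None) -> str:
        payload = asdict(self)
        payload["phenotype_effects"] = [asdict(e) for e in self.phenotype_effects]
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str) -> "SyntheticTruth":
        if text_or_path.lstrip().startswith("{"):
            payload = json.loads(text_or_path)
        else:
            with open(text_or_path) as fh:
                payload = json.load(fh)
        payload["contaminants"] = {
            k: tuple(v) for k, v in payload["contaminants"].items()
        }
        payload["skew_switches"] = {
            k: tuple(v) for k, v in payload.get("skew_switches", {}).items()
        }
        payload["phenotype_effects"] = [
            PlantedEffect(**e) for e in payload.get("phenotype_effects", [])
        ]
        return cls(**payload)


# ------------------------------------------------ batch assignment

def _assign_batches(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_samples
    idx = np.arange(n)
    sample_ids = [f"S{i:05d}" for i in idx]
    meta = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"))
    block = -(-n // config.n_cohorts)          # ceil
    meta["cohort"] = [f"cohort{(i // block) + 1}" for i in idx]
    for v, (var, k) in enumerate(config.batch_variables.items(), start=1):
        vb = -(-n // k)
        if config.assignment == "independent":
            labels = rng.integers(0, k, size=n)
        elif config.assignment == "blocks":
            # contiguous blocks, rotated per variable so successive
            # variables are confounded but not identical
            shift = (v * vb) // 2
            labels = ((idx + shift) % n) // vb
        else:
            raise DataError(f"unknown assignment scheme {config.assignment!r}")
        meta[var] = [f"{var}_b{l + 1}" for l in labels]
    return meta


def _ra_from_uniform(u: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Map U(0,1) to log-uniform relative abundances on [lo, hi]."""
    return lo * (hi / lo) ** u


def simulate_cohort_counts(
    config: SimulationConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate (counts, batch metadata, truth) for the default scenario.

    Per sample the total microbial read count is lognormal; genuine
    species are present independently at their true prevalence with a
    log-uniform relative abundance high enough to clear the presence
    thresholds in the large majority of occurrences; each contaminant is
    present in its home batch with probability
    ``contaminant_home_prevalence``, tied to its co-resident
    contaminants by a shared per-sample latent factor (Gaussian copula),
    and at the background prevalence elsewhere; leftover reads are
    spread thinly (<= ``noise_max_reads`` per entry) across a tail of
    noise species, mimicking read misclassification.
    """
    config = config or SimulationConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    meta = _assign_batches(config, rng)
    samples = meta.index

    genuine_names = [f"genuine_g{i + 1:02d}" for i in range(config.n_genuine_species)]
    contam_names = [f"contam_c{i + 1:02d}" for i in range(config.n_contaminant_species)]
    noise_names = [f"noise_n{i + 1:04d}" for i in range(config.n_noise_species)]
    species = genuine_names + contam_names + noise_names

    totals = np.round(
        rng.lognormal(np.log(config.total_reads_median), config.total_reads_sigma, n)
    ).astype(np.int64)
    totals = np.maximum(totals, 1)

    ra = np.zeros((n, len(species)))

    # genuine species: sporadic, batch-independent
    lo_p, hi_p = config.genuine_prevalence_range
    genuine_prev = rng.uniform(lo_p, hi_p, size=config.n_genuine_species)
    lo_a, hi_a = config.genuine_ra_range
    for j, _ in enumerate(genuine_names):
        present = rng.random(n) < genuine_prev[j]
        k = int(present.sum())
        if k:
            ra[present, j] = _ra_from_uniform(rng.random(k), lo_a, hi_a)

    # contaminants: home batch with copula co-occurrence, background
    # elsewhere
    variables = list(config.batch_variables)
    homes: dict[str, tuple[str, str]] = {}
    for c_idx, name in enumerate(contam_names):
        var = variables[c_idx % len(variables)]
        k_batches = config.batch_variables[var]
        label = f"{var}_b{(c_idx // len(variables)) % k_batches + 1}"
        homes[name] = (var, label)
    rho = config.within_batch_correlation
    q_home = ndtri(config.contaminant_home_prevalence)
    lo_c, hi_c = config.contaminant_ra_range
    by_home: dict[tuple[str, str], list[str]] = {}
    for name, home in homes.items():
        by_home.setdefault(home, []).append(name)
    col = {sp: i for i, sp in enumerate(species)}
    for (var, label), members in sorted(by_home.items()):
        in_batch = (meta[var] == label).to_numpy()
        nb = int(in_batch.sum())
        factor = rng.standard_normal(nb)
        for name in members:
            j = col[name]
            z = np.sqrt(rho) * factor + np.sqrt(1 - rho) * rng.standard_normal(nb)
            present_home = z < q_home
            # conditional-uniform quantile keeps abundance tied to the
            # shared factor: stronger latent load, higher abundance
            u = np.zeros(nb)
            phi = np.clip(
                _norm_cdf(z) / config.contaminant_home_prevalence, 0.0, 1.0
            )
            u[present_home] = 1.0 - phi[present_home]
            ra_home = np.zeros(nb)
            ra_home[present_home] = _ra_from_uniform(
                u[present_home], lo_c, hi_c
            )
            ra[in_batch, j] = ra_home
            # background presence outside the home batch
            out_batch = ~in_batch
            nbg = int(out_batch.sum())
            bg_present = rng.random(nbg) < config.contaminant_background_prevalence
            bg_ra = np.zeros(nbg)
            kbg = int(bg_present.sum())
            if kbg:
                bg_ra[bg_present] = _ra_from_uniform(rng.random(kbg), lo_c, hi_c)
            ra[out_batch, j] = bg_ra

    # keep planted fractions feasible: cap the per-sample planted load
    planted_sum = ra.sum(axis=1)
    over = planted_sum > 0.8
    if over.any():
        ra[over] *= (0.8 / planted_sum[over])[:, None]

    counts = np.zeros((n, len(species)), dtype=np.int64)
    n_planted = len(genuine_names) + len(contam_names)
    counts[:, :n_planted] = np.round(ra[:, :n_planted] * totals[:, None])

    # residual reads scattered over the noise tail, capped per entry
    if config.n_noise_species:
        propensity = rng.dirichlet(np.ones(config.n_noise_species))
        residual = np.maximum(totals - counts.sum(axis=1), 0)
        noise = rng.multinomial(residual, propensity)
        counts[:, n_planted:] = np.minimum(noise, config.noise_max_reads)

    counts_df = pd.DataFrame(counts, index=samples, columns=species)
    truth = SyntheticTruth(
        contaminants=homes,
        genuine={name: float(genuine_prev[j]) for j, name in enumerate(genuine_names)},
        noise_species=noise_names,
    )
    return counts_df, meta, truth


def _norm_cdf(z: np.ndarray) -> np.ndarray:
    from scipy.special import ndtr
    return ndtr(z)


# ------------------------------------------------ phenotypes

#: marginal distributions typical of an adult Asian population survey
PHENOTYPE_MARGINALS = {
    "age": ("uniform", 21.0, 80.0),
    "bmi": ("truncnorm", 24.0, 4.0, 14.0, np.inf),
    "tc": ("truncnorm", 5.2, 1.1, 1.0, np.inf),      # mmol/l
    "tg": ("truncnorm", 1.5, 0.8, 0.2, np.inf),      # mmol/l
    "sbp": ("truncnorm", 125.0, 15.0, 70.0, np.inf),  # mmHg
    "dbp": ("truncnorm", 75.0, 10.0, 40.0, np.inf),   # mmHg
}
ANCESTRY_LEVELS = ("Chinese", "Malay", "Indian", "Others")
ANCESTRY_PROBS = (0.57, 0.22, 0.16, 0.05)

_CONDITION_SOURCES = {
    "elderly": ("age", "ge", 65.0),
    "obese": ("bmi", "gt", 30.0),
    "high_tg": ("tg", "gt", 2.3),
    "high_tc": ("tc", "ge", 6.3),
}


def _draw_marginal(name: str, size: int, rng: np.random.Generator) -> np.ndarray:
    kind, *params = PHENOTYPE_MARGINALS[name]
    if kind == "uniform":
        lo, hi = params
        return rng.uniform(lo, hi, size)
    mu, sd, lo, hi = params
    a, b = (lo - mu) / sd, (hi - mu) / sd if np.isfinite(hi) else np.inf
    return truncnorm.rvs(a, b, loc=mu, scale=sd, size=size, random_state=rng)


def _draw_conditional(
    name: str, op: str, threshold: float, above: bool, size: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw a phenotype value conditional on being above/below threshold."""
    kind, *params = PHENOTYPE_MARGINALS[name]
    if kind == "uniform":
        lo, hi = params
        if above:
            return rng.uniform(threshold, hi, size)
        return rng.uniform(lo, threshold, size)
    mu, sd, lo, hi = params
    if above:
        a, b = (threshold - mu) / sd, np.inf
    else:
        a, b = (lo - mu) / sd, (threshold - mu) / sd
    return truncnorm.rvs(a, b, loc=mu, scale=sd, size=size, random_state=rng)


def simulate_phenotypes(
    meta: pd.DataFrame,
    effects: list[PlantedEffect] | None = None,
    presence: pd.DataFrame | None = None,
    seed: int | None = None,
    missing_rate: float = 0.0,
) -> pd.DataFrame:
    """Draw host phenotypes, optionally planting presence effects.

    Effects re-draw the source column for carriers so that the derived
    condition's odds shift by ``log_odds`` while the conditional shape
    within each side of the threshold is preserved.  Effects referencing
    species absent from *presence* are an error.
    """
    rng = np.random.default_rng(seed)
    n = len(meta)
    pheno = pd.DataFrame(index=meta.index)
    pheno["sex"] = rng.choice(["F", "M"], size=n)
    pheno["ancestry"] = rng.choice(ANCESTRY_LEVELS, size=n, p=ANCESTRY_PROBS)
    for name in PHENOTYPE_MARGINALS:
        pheno[name] = _draw_marginal(name, n, rng)
    pheno["cohort"] = meta["cohort"] if "cohort" in meta.columns else "cohort1"

    for eff in effects or []:
        if presence is None:
            raise DataError("planting effects requires a presence matrix")
        if eff.species not in presence.columns:
            raise DataError(f"planted effect on unknown species {eff.species!r}")
        if eff.condition not in _CONDITION_SOURCES:
            raise DataError(f"unsupported planted condition {eff.condition!r}")
        name, op, thr = _CONDITION_SOURCES[eff.condition]
        vals = pheno[name].to_numpy()
        above = vals > thr if op == "gt" else vals >= thr
        q = float(above.mean())
        carriers = presence.loc[meta.index, eff.species].to_numpy(dtype=bool)
        k = int(carriers.sum())
        if k == 0:
            continue
        q_new = float(expit(logit(q) + eff.log_odds))
        flag = rng.random(k) < q_new
        redrawn = np.empty(k)
        if flag.any():
            redrawn[flag] = _draw_conditional(name, op, thr, True, int(flag.sum()), rng)
        if (~flag).any():
            redrawn[~flag] = _draw_conditional(
                name, op, thr, False, int((~flag).sum()), rng
            )
        vals[carriers] = redrawn
        pheno[name] = vals

    if missing_rate > 0:
        for name in PHENOTYPE_MARGINALS:
            mask = rng.random(n) < missing_rate
            pheno.loc[mask, name] = np.nan
    return pheno


# ------------------------------------------------ coverage & genomes

def _piecewise_log2_shape(
    n_bins: int, ori_bin: float, ter_bin: float, log2_range: float
) -> np.ndarray:
    """Expected log2 depth: linear peak-at-ori to trough-at-ter, both arcs."""
    k = np.arange(n_bins)
    arc = (ter_bin - ori_bin) % n_bins
    fwd = (k - ori_bin) % n_bins
    frac = np.where(
        fwd <= arc,
        np.divide(fwd, arc, out=np.zeros_like(fwd, dtype=float), where=arc > 0),
        np.divide(n_bins - fwd, n_bins - arc,
                  out=np.zeros_like(fwd, dtype=float), where=(n_bins - arc) > 0),
    )
    return -log2_range * frac          # 0 at ori, -log2_range at ter


def simulate_coverage(
    length: int,
    ptr: float,
    ori: float,
    ter: float,
    mean_depth: float,
    bin_size: int = 10_000,
    seed: int | None = None,
    genome_id: str = "sim_genome",
) -> CoverageTrack:
    """Poisson-sampled circular coverage with a planted PTR.

    The expected log2 depth is piecewise linear on the circle, maximal
    at *ori* and minimal at *ter* with ``log2(peak/trough) =
    log2(ptr)``, scaled so the expected mean depth equals *mean_depth*;
    each bin's observed depth is Poisson(expected x bin_size)/bin_size.
    """
    if ptr < 1.0:
        raise DataError("planted ptr must be >= 1")
    if ori == ter:
        raise DataError("ori and ter must differ")
    n_bins = length // bin_size
    if n_bins < 2:
        raise DataError("genome too short for the requested bin size")
    rng = np.random.default_rng(seed)
    shape = _piecewise_log2_shape(
        n_bins, ori / bin_size, ter / bin_size, np.log2(ptr)
    )
    expected = 2.0 ** shape
    expected *= mean_depth / expected.mean()
    lam = expected * bin_size
    depth = rng.poisson(lam).astype(float) / bin_size
    return CoverageTrack(
        genome_id=genome_id, length=n_bins * bin_size, depth=depth,
        circular=True, bin_size=bin_size,
    )


def simulate_genome_with_skew(
    length: int,
    ori: float,
    ter: float,
    skew_amplitude: float,
    gc_content: float = 0.5,
    seed: int | None = None,
) -> str:
    """Random circular genome whose GC skew switches sign at ori and ter.

    G/C positions on the ori->ter arc (the leading-strand segment going
    forward from the origin) have ``P(G) = (1 + amplitude)/2``; the
    complementary arc has ``P(G) = (1 - amplitude)/2``.  Under the
    cumulative-skew convention this puts the minimum at *ori* and the
    maximum at *ter*.  ``skew_amplitude=0`` yields a skew-free genome.
    """
    if not (0.0 <= skew_amplitude <= 1.0):
        raise DataError("skew_amplitude must lie in [0, 1]")
    if not (0.0 < gc_content < 1.0):
        raise DataError("gc_content must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    pos = np.arange(length)
    ori_i, ter_i = int(ori) % length, int(ter) % length
    if ori_i <= ter_i:
        leading = (pos >= ori_i) & (pos < ter_i)
    else:
        leading = (pos >= ori_i) | (pos < ter_i)
    is_gc = rng.random(length) < gc_content
    p_g = np.where(leading, (1.0 + skew_amplitude) / 2.0,
                   (1.0 - skew_amplitude) / 2.0)
    g = rng.random(length) < p_g
    a = rng.random(length) < 0.5
    seq = np.where(is_gc, np.where(g, b"G", b"C"), np.where(a, b"A", b"T"))
    return seq.tobytes().decode("ascii")


# ------------------------------------------------ basis counts for SparCC

def simulate_correlated_counts(
    n_samples: int = 500,
    n_species: int = 20,
    correlated_pairs: list[tuple[int, int, float]] | None = None,
    total_reads: int = 50_000,
    basis_sigma: float = 1.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Multinomial counts from lognormal basis abundances.

    Basis log-abundances are independent normals except for the listed
    ``(i, j, r)`` pairs, where species j's log-abundance is given
    correlation r with species i's.  Used to benchmark compositional
    correlation estimators against a known basis correlation.
    """
    rng = np.random.default_rng(seed)
    mu = rng.normal(0.0, 1.0, n_species)
    z = rng.standard_normal((n_samples, n_species))
    for i, j, r in correlated_pairs or []:
        if not (-1.0 < r < 1.0):
            raise DataError("pair correlation must lie in (-1, 1)")
        z[:, j] = r * z[:, i] + np.sqrt(1.0 - r * r) * z[:, j]
    log_abund = mu + basis_sigma * z
    frac = np.exp(log_abund)
    frac /= frac.sum(axis=1, keepdims=True)
    counts = np.vstack([rng.multinomial(total_reads, f) for f in frac])
    return pd.DataFrame(
        counts,
        index=[f"S{i:04d}" for i in range(n_samples)],
        columns=[f"sp{j + 1:02d}" for j in range(n_species)],
    )
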