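"""Batch-aware decontamination of presence-called blood metagenomes.

Low-biomass sequencing is dominated by reagent-kit ("kitome") DNA whose
hallmark is batch structure: contaminants are highly prevalent in the
laboratory batches whose reagents carry them, correlate with each other
within a batch, and do not recur across independent reagent lots.  Four
heuristic filters exploit this, applied sequentially to the survivor set
of the previous stage:

1. *Prevalence filter* — a species is a contaminant specific to a batch
   when its prevalence there exceeds 25% and is more than twofold its
   prevalence in every other (>=100-sample) batch of the same variable.
2. *Correlation filter* — a species whose centred-log-ratio abundances
   have Spearman rho > 0.7 with any prevalence-filter contaminant over
   the samples of that contaminant's batch is also called.
3. *Batch filter* — a genuine species must be detected in at least two
   batches of every reagent variable; single-batch species are called.
4. *Read-count filter* — a species never reaching 100 read pairs in any
   single sample is an analysis artefact.

A species flagged by any filter in any batch is removed globally.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import DataError
from .profiles import PresenceMatrix

PREV_THRESHOLD = 0.25
PREV_FOLD = 2.0
MIN_BATCH_SIZE = 100
RHO_THRESHOLD = 0.7
MIN_MAX_READS = 100

FILTER_NAMES = ("prevalence", "correlation", "batch", "read_count")


@dataclass
class ContaminantCall:
    """One (species, filter) contaminant call with its audit evidence."""

    species: str
    filter: str                       # one of FILTER_NAMES
    batch_variable: str | None = None
    batch_label: str | None = None
    evidence: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.filter not in FILTER_NAMES:
            raise DataError(f"unknown filter {self.filter!r}")
        if self.filter == "prevalence" and (
            self.batch_variable is None or self.batch_label is None
        ):
            raise DataError("prevalence calls must name a batch")
        if self.filter == "read_count" and (
            self.batch_variable is not None or self.batch_label is not None
        ):
            raise DataError("read_count calls are batch-free")


@dataclass
class DecontamReport:
    """Ordered record of contaminant calls and the surviving species list."""

    calls: list[ContaminantCall]
    species_before: int
    species_after_each_filter: list[int]
    survivors: list[str]
    filter_names: tuple[str, ...] = FILTER_NAMES

    def called_species(self) -> set[str]:
        return {c.species for c in self.calls}

    def calls_by_filter(self) -> dict[str, list[ContaminantCall]]:
        out: dict[str, list[ContaminantCall]] = {f: [] for f in self.filter_names}
        for c in self.calls:
            out[c.filter].append(c)
        return out

    def to_json(self, path: str | None = None) -> str:
        payload = {
            "species_before": self.species_before,
            "species_after_each_filter": self.species_after_each_filter,
            "filter_names": list(self.filter_names),
            "survivors": self.survivors,
            "calls": [asdict(c) for c in self.calls],
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def calls_table(self) -> pd.DataFrame:
        rows = [
            {
                "species": c.species,
                "filter": c.filter,
                "batch_variable": c.batch_variable,
                "batch_label": c.batch_label,
                "evidence": json.dumps(c.evidence, sort_keys=True),
            }
            for c in self.calls
        ]
        return pd.DataFrame(
            rows, columns=["species", "filter", "batch_variable", "batch_label", "evidence"]
        )


@dataclass
class DecontamConfig:
    """Thresholds and switches for the four-filter chain."""

    variables: list[str] | None = None          # None -> all metadata columns
    min_batch_size: int = MIN_BATCH_SIZE
    prev_threshold: float = PREV_THRESHOLD
    fold: float = PREV_FOLD
    rho_threshold: float = RHO_THRESHOLD
    excluded_variables: tuple[str, ...] = ("library_kit",)
    min_max_reads: int = MIN_MAX_READS
    enable_prevalence: bool = True
    enable_correlation: bool = True
    enable_batch: bool = True
    enable_read_count: bool = True
    zero_replacement_factor: float = 0.65


# ------------------------------------------------------------ helpers

def prevalence_by_batch(
    present: pd.DataFrame, meta: pd.DataFrame, variable: str
) -> pd.DataFrame:
    """Per-species prevalence within each batch of one metadata variable.

    Returns a long table (species, batch_label, prevalence, n_samples);
    batches appear even when a species' prevalence there is zero.
    """
    if variable not in meta.columns:
        raise DataError(f"unknown batch variable {variable!r}")
    labels = meta.loc[present.index, variable]
    grouped = present.groupby(labels, observed=True).mean()
    sizes = labels.value_counts()
    long = grouped.stack().rename("prevalence").reset_index()
    long.columns = ["batch_label", "species", "prevalence"]
    long["n_samples"] = long["batch_label"].map(sizes).astype(int)
    return long[["species", "batch_label", "prevalence", "n_samples"]]


def prevalence_filter(
    present: pd.DataFrame,
    meta: pd.DataFrame,
    variables: list[str],
    min_batch_size: int = MIN_BATCH_SIZE,
    prev_threshold: float = PREV_THRESHOLD,
    fold: float = PREV_FOLD,
) -> list[ContaminantCall]:
    """Call batch-specific contaminants from prevalence imbalance.

    A species is called in batch ``b`` of a variable when its prevalence
    there strictly exceeds *prev_threshold* and strictly exceeds
    ``fold x`` its prevalence in every other eligible batch of the same
    variable.  Batches below *min_batch_size* samples are excluded from
    both sides of the comparison; a variable with fewer than two eligible
    batches is skipped with a warning.
    """
    if min_batch_size < 1:
        raise DataError("min_batch_size must be >= 1")
    calls: list[ContaminantCall] = []
    for variable in variables:
        if variable not in meta.columns:
            raise DataError(f"unknown batch variable {variable!r}")
        labels = meta.loc[present.index, variable]
        sizes = labels.value_counts()
        eligible = sizes.index[sizes >= min_batch_size]
        if len(eligible) < 2:
            warnings.warn(
                f"variable {variable!r}: fewer than 2 batches with >= "
                f"{min_batch_size} samples; prevalence filter skipped",
                stacklevel=2,
            )
            continue
        prev = present.groupby(labels, observed=True).mean().loc[eligible]
        arr = prev.to_numpy()                      # batches x species
        for i, batch in enumerate(eligible):
            others = np.delete(arr, i, axis=0)
            max_other = others.max(axis=0)
            hit = (arr[i] > prev_threshold) & (arr[i] > fold * max_other)
            for j in np.flatnonzero(hit):
                calls.append(
                    ContaminantCall(
                        species=prev.columns[j],
                        filter="prevalence",
                        batch_variable=variable,
                        batch_label=str(batch),
                        evidence={
                            "prevalence_in_batch": float(arr[i, j]),
                            "n_samples": int(sizes[batch]),
                            "max_other_prevalence": float(max_other[j]),
                            "prev_threshold": prev_threshold,
                            "fold": fold,
                        },
                    )
                )
    return calls


def clr_transform(
    abund: pd.DataFrame,
    zero_replacement: str = "multiplicative",
    zero_factor: float = 0.65,
    allow_zero_rows: bool = False,
) -> pd.DataFrame:
    """Centred log-ratio transform of relative abundances.

    Zeros are first replaced by ``zero_factor`` times the smallest
    nonzero value of the matrix (multiplicative simple replacement); each
    row then maps to ``ln(x) - mean(ln(x))`` and sums to zero.  Rows that
    are entirely zero are an error unless *allow_zero_rows* is set, in
    which case they come out as all-zero CLR rows (every entry equal
    after replacement).
    """
    if abund.shape[1] < 2:
        raise DataError("clr_transform requires at least 2 species")
    if zero_replacement != "multiplicative":
        raise DataError(f"unknown zero replacement {zero_replacement!r}")
    x = abund.to_numpy(dtype=float).copy()
    if (x < 0).any():
        raise DataError("negative abundances")
    zero_rows = ~(x > 0).any(axis=1)
    if zero_rows.any() and not allow_zero_rows:
        bad = abund.index[zero_rows].tolist()
        raise DataError(f"rows with all-zero abundance: {bad[:5]}")
    nonzero = x[x > 0]
    if nonzero.size == 0:
        raise DataError("matrix is entirely zero")
    x[x == 0] = zero_factor * nonzero.min()
    logx = np.log(x)
    clr = logx - logx.mean(axis=1, keepdims=True)
    return pd.DataFrame(clr, index=abund.index, columns=abund.columns)


def _spearman_against(
    mat: np.ndarray, seeds: np.ndarray
) -> np.ndarray:
    """Spearman correlations (mid-rank convention) seeds x all columns."""
    n = mat.shape[0]
    r_all = np.apply_along_axis(rankdata, 0, mat)
    r_seed = np.apply_along_axis(rankdata, 0, seeds)
    za = r_all - r_all.mean(axis=0)
    zs = r_seed - r_seed.mean(axis=0)
    sa = np.sqrt((za ** 2).sum(axis=0))
    ss = np.sqrt((zs ** 2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (zs.T @ za) / np.outer(ss, sa)
    return rho


def correlation_filter(
    abund: pd.DataFrame,
    meta: pd.DataFrame,
    seed_calls: list[ContaminantCall],
    rho_threshold: float = RHO_THRESHOLD,
    candidates: list[str] | None = None,
    zero_factor: float = 0.65,
    min_batch_samples: int = 3,
) -> list[ContaminantCall]:
    """Call species rank-correlated with a known contaminant in its batch.

    For every prevalence-filter seed call (contaminant c in batch b),
    Spearman's rho between CLR-transformed abundances of each candidate
    and c is computed over exactly the samples of b; a candidate is
    called when rho strictly exceeds *rho_threshold* for any seed.
    Batches with fewer than *min_batch_samples* samples are skipped with
    a warning (rank correlation is degenerate there).
    """
    if not seed_calls:
        return []
    clr = clr_transform(abund, zero_factor=zero_factor, allow_zero_rows=True)
    seed_species = {c.species for c in seed_calls}
    if candidates is None:
        candidates = [s for s in abund.columns if s not in seed_species]
    else:
        candidates = [s for s in candidates if s not in seed_species]
    calls: dict[str, ContaminantCall] = {}
    by_batch: dict[tuple[str, str], list[str]] = {}
    for c in seed_calls:
        by_batch.setdefault((c.batch_variable, c.batch_label), []).append(c.species)
    for (variable, batch), seeds in sorted(by_batch.items()):
        samples = meta.index[meta[variable].astype(str) == batch]
        samples = samples.intersection(abund.index)
        if len(samples) < min_batch_samples:
            warnings.warn(
                f"batch {variable}={batch}: only {len(samples)} samples; "
                "correlation filter skipped for this batch",
                stacklevel=2,
            )
            continue
        seeds = sorted(set(seeds))
        sub = clr.loc[samples]
        rho = _spearman_against(
            sub[candidates].to_numpy(), sub[seeds].to_numpy()
        )
        with np.errstate(invalid="ignore"):
            hit_seed, hit_cand = np.nonzero(np.nan_to_num(rho) > rho_threshold)
        for si, ci in zip(hit_seed, hit_cand):
            sp = candidates[ci]
            if sp in calls:
                continue
            calls[sp] = ContaminantCall(
                species=sp,
                filter="correlation",
                batch_variable=variable,
                batch_label=batch,
                evidence={
                    "rho": float(rho[si, ci]),
                    "partner_species": seeds[si],
                    "n_samples": int(len(samples)),
                    "rho_threshold": rho_threshold,
                },
            )
    return [calls[s] for s in sorted(calls)]


def batch_filter(
    present: pd.DataFrame,
    meta: pd.DataFrame,
    variables: list[str],
    excluded_variables: tuple[str, ...] = ("library_kit",),
) -> list[ContaminantCall]:
    """Call species detected in at most one batch of any reagent variable.

    Species present in zero samples are called too (degenerate
    single-batch case, evidence notes zero detections).
    """
    used = [v for v in variables if v not in set(excluded_variables)]
    if not used:
        raise DataError("batch filter: all variables excluded")
    for v in used:
        if v not in meta.columns:
            raise DataError(f"unknown batch variable {v!r}")
    calls: dict[str, ContaminantCall] = {}
    n_present = present.sum(axis=0)
    for variable in used:
        labels = meta.loc[present.index, variable]
        detected = present.groupby(labels, observed=True).any()  # batch x species
        n_batches = detected.sum(axis=0)
        for sp in present.columns[(n_batches <= 1)]:
            if sp in calls:
                continue
            hit = detected.index[detected[sp]] if n_batches[sp] == 1 else []
            calls[sp] = ContaminantCall(
                species=sp,
                filter="batch",
                batch_variable=variable,
                batch_label=str(hit[0]) if len(hit) else None,
                evidence={
                    "n_batches_detected": int(n_batches[sp]),
                    "n_samples_present": int(n_present[sp]),
                },
            )
    return [calls[s] for s in sorted(calls)]


def read_count_filter(
    zeroed_counts: pd.DataFrame, min_max_reads: int = MIN_MAX_READS
) -> list[ContaminantCall]:
    """Call species never assigned *min_max_reads* reads in any sample."""
    max_reads = zeroed_counts.max(axis=0)
    n_present = (zeroed_counts > 0).sum(axis=0)
    calls = []
    for sp in zeroed_counts.columns[max_reads < min_max_reads]:
        calls.append(
            ContaminantCall(
                species=sp,
                filter="read_count",
                evidence={
                    "max_reads": int(max_reads[sp]),
                    "n_samples_detected": int(n_present[sp]),
                    "min_max_reads": min_max_reads,
                },
            )
        )
    return calls


def run_decontamination(
    presence: PresenceMatrix,
    meta: pd.DataFrame,
    config: DecontamConfig | None = None,
    species: list[str] | None = None,
) -> DecontamReport:
    """Apply the four filters in order and report survivors.

    *species* restricts the starting set (by default every species
    detected in at least one sample); a species called by any filter is
    removed globally.  The correlation filter is seeded exclusively by
    prevalence-filter calls, and each stage operates on the survivor set
    of the previous one.
    """
    config = config or DecontamConfig()
    variables = config.variables or list(meta.columns)
    if species is None:
        species = presence.species_detected()
    survivors = list(species)
    before = len(survivors)
    all_calls: list[ContaminantCall] = []
    after_each: list[int] = []

    # relative abundances consistent with the presence calls: zeroed
    # counts over the original per-sample totals
    abund = presence.zeroed_counts.div(presence.totals, axis=0)

    def _apply(calls: list[ContaminantCall]) -> None:
        nonlocal survivors
        called = {c.species for c in calls}
        all_calls.extend(calls)
        survivors = [s for s in survivors if s not in called]
        after_each.append(len(survivors))

    # 1. prevalence
    if config.enable_prevalence and survivors:
        calls = prevalence_filter(
            presence.present[survivors], meta,
            variables, config.min_batch_size,
            config.prev_threshold, config.fold,
        )
    else:
        calls = []
    seed_calls = calls
    _apply(calls)

    # 2. correlation (seeded only by prevalence calls)
    if config.enable_correlation and seed_calls and survivors:
        seed_cols = sorted({c.species for c in seed_calls})
        calls = correlation_filter(
            abund[survivors + seed_cols], meta, seed_calls,
            rho_threshold=config.rho_threshold,
            candidates=survivors,
            zero_factor=config.zero_replacement_factor,
        )
    else:
        calls = []
    _apply(calls)

    # 3. batch
    if config.enable_batch and survivors:
        calls = batch_filter(
            presence.present[survivors], meta, variables,
            excluded_variables=config.excluded_variables,
        )
    else:
        calls = []
    _apply(calls)

    # 4. read count
    if config.enable_read_count and survivors:
        calls = read_count_filter(
            presence.zeroed_counts[survivors], config.min_max_reads
        )
    else:
        calls = []
    _apply(calls)

    return DecontamReport(
        calls=all_calls,
        species_before=before,
        species_after_each_filter=after_each,
        survivors=survivors,
    )
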