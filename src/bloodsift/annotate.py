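"""Species annotation joins and the randomization enrichment test.

Decontamination is validated by asking whether the surviving species
look more biological than chance: compared with random same-sized draws
from the pre-filter species list, the survivors should contain fewer
known sequencing contaminants and more species with blood-culture
records or human association.  The null distribution is built by
repeatedly drawing survivor-sized subsets uniformly without replacement,
so it is exactly hypergeometric in the number of category-positive
species — a property the test suite exploits as an oracle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError

CONTAMINANT_CLASSES = (
    "likely_contaminant", "mixed_evidence", "pathogen_commensal", "unknown"
)
GROWTH_CLASSES = (
    "obligate_anaerobe", "obligate_intracellular", "facultative", "aerobe",
    "unknown",
)
CATEGORIES = ("likely_contaminant", "in_blood_culture", "human_associated")


def read_annotation_tsv(path: str) -> pd.DataFrame:
    """Read a species annotation table.

    Columns: species, contaminant_class, in_blood_culture (0/1),
    human_associated (0/1), body_sites (semicolon-separated, may be
    empty), growth.
    """
    db = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"species", "contaminant_class", "in_blood_culture",
                "human_associated", "body_sites", "growth"}
    missing = required - set(db.columns)
    if missing:
        raise DataError(f"{path}: missing annotation columns {sorted(missing)}")
    if db["species"].duplicated().any():
        raise DataError(f"{path}: duplicate species rows")
    db = db.set_index("species")
    for col in ("contaminant_class", "growth"):
        db[col] = db[col].replace("", "unknown")
    bad = set(db["contaminant_class"]) - set(CONTAMINANT_CLASSES)
    if bad:
        raise DataError(f"{path}: unknown contaminant_class values {sorted(bad)}")
    bad = set(db["growth"]) - set(GROWTH_CLASSES)
    if bad:
        raise DataError(f"{path}: unknown growth values {sorted(bad)}")
    for col in ("in_blood_culture", "human_associated"):
        db[col] = db[col].replace("", "0").astype(int).astype(bool)
    db["body_sites"] = db["body_sites"].map(
        lambda s: frozenset(x.strip() for x in s.split(";") if x.strip())
    )
    return db


def write_annotation_tsv(db: pd.DataFrame, path: str) -> None:
    out = db.copy()
    out["in_blood_culture"] = out["in_blood_culture"].astype(int)
    out["human_associated"] = out["human_associated"].astype(int)
    out["body_sites"] = out["body_sites"].map(lambda s: ";".join(sorted(s)))
    out.to_csv(path, sep="\t", index_label="species")


def _category_flags(species: list[str], db: pd.DataFrame, category: str) -> np.ndarray:
    """Boolean flag per species; species missing from the db are negative."""
    if category == "likely_contaminant":
        col = db["contaminant_class"] == "likely_contaminant"
    elif category in ("in_blood_culture", "human_associated"):
        col = db[category].astype(bool)
    else:
        raise DataError(f"unknown annotation category {category!r}")
    return np.array([bool(col.get(sp, False)) for sp in species])


def classify_proportions(species_list: list[str], db: pd.DataFrame) -> dict[str, float]:
    """Proportion of a species list falling in each annotation category.

    Species absent from the db count as category-negative but stay in
    the denominator; their fraction is reported under ``"unknown"``.
    """
    if not species_list:
        raise DataError("classify_proportions: empty species list")
    n = len(species_list)
    out = {
        cat: _category_flags(species_list, db, cat).sum() / n
        for cat in CATEGORIES
    }
    out["unknown"] = sum(sp not in db.index for sp in species_list) / n
    return out


@dataclass
class RandomizationResult:
    """Observed category proportion against random same-size species draws."""

    category: str
    observed_proportion: float
    null_proportions: np.ndarray
    p_value: float
    direction: str
    n_iter: int
    seed: int | None

    def p_text(self) -> str:
        """Human-readable p, reporting exact zeros as a bound."""
        if self.p_value == 0.0:
            return f"< {1.0 / self.n_iter:g}"
        return f"{self.p_value:g}"

    def to_dict(self) -> dict:
        return {
            "category": self.category,
            "observed_proportion": self.observed_proportion,
            "p_value": self.p_value,
            "p_text": self.p_text(),
            "direction": self.direction,
            "n_iter": self.n_iter,
            "seed": self.seed,
            "null_proportions": [float(x) for x in self.null_proportions],
        }


def randomization_test(
    pre_list: list[str],
    post_list: list[str],
    db: pd.DataFrame,
    category: str,
    direction: str = "greater",
    n_iter: int = 1000,
    seed: int | None = None,
) -> RandomizationResult:
    """Test whether filtering shifted a category proportion beyond chance.

    Draws *n_iter* uniform subsets of size ``len(post_list)`` from
    *pre_list* without replacement and reports the plain fraction of
    iterations whose category proportion is as extreme or more extreme
    than the observed one (>= for ``direction="greater"``, <= for
    ``"less"``).
    """
    if not post_list:
        raise DataError("randomization_test: empty post-filter list")
    post_set = set(post_list)
    if not post_set <= set(pre_list):
        raise DataError("post_list must be a subset of pre_list")
    if len(post_list) > len(pre_list):
        raise DataError("post_list larger than pre_list")
    if direction not in ("greater", "less"):
        raise DataError(f"unknown direction {direction!r}")
    flags = _category_flags(list(pre_list), db, category)
    observed = _category_flags(list(post_list), db, category).mean()
    rng = np.random.default_rng(seed)
    k = len(post_list)
    null = np.empty(n_iter)
    for i in range(n_iter):
        idx = rng.choice(len(pre_list), size=k, replace=False)
        null[i] = flags[idx].mean()
    if direction == "greater":
        p = float(np.mean(null >= observed - 1e-12))
    else:
        p = float(np.mean(null <= observed + 1e-12))
    return RandomizationResult(
        category=category,
        observed_proportion=float(observed),
        null_proportions=null,
        p_value=p,
        direction=direction,
        n_iter=n_iter,
        seed=seed,
    )


DEFAULT_DIRECTIONS = {
    # filters should deplete known contaminants and enrich the biological
    # categories
    "likely_contaminant": "less",
    "in_blood_culture": "greater",
    "human_associated": "greater",
}


def enrichment_suite(
    pre_list: list[str],
    post_list: list[str],
    db: pd.DataFrame,
    n_iter: int = 1000,
    seed: int | None = None,
) -> dict[str, RandomizationResult]:
    """Run the three standard one-sided randomization tests."""
    out = {}
    for i, (cat, direction) in enumerate(sorted(DEFAULT_DIRECTIONS.items())):
        sub_seed = None if seed is None else seed + i
        out[cat] = randomization_test(
            pre_list, post_list, db, cat, direction, n_iter, sub_seed
        )
    return out


def prevalence_table(
    present: pd.DataFrame,
    groupings: dict[str, str] | None = None,
) -> pd.Series:
    """Fraction of all samples in which each species (or group) is present.

    With a species-to-group mapping (e.g. species to genus), a group is
    present in a sample when any member species is.
    """
    if groupings is None:
        prev = present.mean(axis=0)
        prev.name = "prevalence"
        return prev
    cols = [sp for sp in present.columns if sp in groupings]
    grouped = present[cols].T.groupby(
        pd.Series({sp: groupings[sp] for sp in cols})
    ).any().T
    prev = grouped.mean(axis=0)
    prev.name = "prevalence"
    return prev


@dataclass
class SpeciesSummary:
    """Per-sample species richness after decontamination."""

    per_sample: pd.Series          # number of present species per sample
    zero_fraction: float           # fraction of samples with no species
    median_nonzero: float | None   # median count among samples with >= 1
    histogram: pd.Series           # species-count -> number of samples

    def to_dict(self) -> dict:
        return {
            "zero_fraction": self.zero_fraction,
            "median_nonzero": self.median_nonzero,
            "histogram": {int(k): int(v) for k, v in self.histogram.items()},
        }


def species_summary(present: pd.DataFrame) -> SpeciesSummary:
    """Summarise how many species are detected per sample."""
    counts = present.sum(axis=1).astype(int)
    zero_fraction = float((counts == 0).mean()) if len(counts) else 0.0
    nonzero = counts[counts > 0]
    median_nonzero = float(nonzero.median()) if len(nonzero) else None
    hist = counts.value_counts().sort_index()
    return SpeciesSummary(
        per_sample=counts,
        zero_fraction=zero_fraction,
        median_nonzero=median_nonzero,
        histogram=hist,
    )


def write_enrichment_json(results: dict[str, RandomizationResult], path: str) -> None:
    payload = {cat: r.to_dict() for cat, r in results.items()}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
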