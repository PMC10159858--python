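"""Shared fixtures: tiny labelled annotation universes and count matrices."""

import numpy as np
import pandas as pd
import pytest


def make_annotation_db(
    n_species: int = 200,
    n_contaminant: int = 0,
    n_blood_culture: int = 0,
    n_human: int = 0,
    prefix: str = "sp",
) -> pd.DataFrame:
    """Deterministic annotation table: the first k species carry each label."""
    idx = [f"{prefix}{i:03d}" for i in range(n_species)]
    db = pd.DataFrame(
        {
            "contaminant_class": [
                "likely_contaminant" if i < n_contaminant else "pathogen_commensal"
                for i in range(n_species)
            ],
            "in_blood_culture": [i < n_blood_culture for i in range(n_species)],
            "human_associated": [i < n_human for i in range(n_species)],
            "body_sites": [frozenset() for _ in range(n_species)],
            "growth": ["unknown"] * n_species,
        },
        index=pd.Index(idx, name="species"),
    )
    return db


@pytest.fixture
def labelled_universe():
    """200 species, 100 positive for blood culture (hypergeometric oracle)."""
    return make_annotation_db(200, n_blood_culture=100)


@pytest.fixture
def small_counts():
    """3 samples x 4 species with easily checked totals."""
    return pd.DataFrame(
        [[10, 30, 60, 0], [0, 50, 50, 0], [5, 5, 0, 0]],
        index=pd.Index(["A", "B", "C"], name="sample_id"),
        columns=["sp1", "sp2", "sp3", "sp4"],
    )


@pytest.fixture
def batch_meta():
    """Two batches of one variable over six samples."""
    return pd.DataFrame(
        {"cohort": ["c1"] * 6, "kit": ["K1", "K1", "K1", "K2", "K2", "K2"]},
        index=pd.Index([f"S{i}" for i in range(6)], name="sample_id"),
    )


def presence_frame(bools, samples=None, species=None) -> pd.DataFrame:
    arr = np.asarray(bools, dtype=bool)
    samples = samples or [f"S{i}" for i in range(arr.shape[0])]
    species = species or [f"sp{j}" for j in range(arr.shape[1])]
    return pd.DataFrame(arr, index=pd.Index(samples, name="sample_id"),
                        columns=species)
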