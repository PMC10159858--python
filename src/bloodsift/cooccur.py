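"""SparCC co-occurrence networks over decontaminated species profiles.

Read counts are compositional: closure to relative abundance induces
spurious negative correlation, so Pearson/Spearman on fractions is
biased for sparse communities.  SparCC instead works from log-ratio
variances ``t_ij = var(ln(x_i/x_j))``, which are invariant to the
per-sample total.  Writing ``t_ij = w_i + w_j - 2 rho_ij sqrt(w_i w_j)``
(with ``w_i`` the basis log-abundance variances) and assuming the
correlation network is sparse (most ``rho_ij ~ 0``), the row sums of
``t`` give a linear system for the basis variances:

    sum_{j in S_i} t_ij = |S_i| w_i + sum_{j in S_i} w_j

which is solved, correlations are formed, and the single strongest pair
above an exclusion threshold is iteratively removed from the sums to
protect the sparsity assumption.  Fractions are estimated from counts by
Dirichlet posterior draws (or the posterior mean in deterministic mode)
and the final correlation is averaged over draws.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd

from .errors import DataError
from .profiles import PresenceMatrix


def select_network_samples(
    presence: PresenceMatrix | pd.DataFrame,
    counts: pd.DataFrame,
    min_species: int = 2,
) -> pd.DataFrame:
    """Keep samples carrying at least *min_species* present species."""
    present = presence.present if isinstance(presence, PresenceMatrix) else presence
    n_species = present.loc[counts.index, counts.columns].sum(axis=1)
    keep = n_species >= min_species
    if not keep.any():
        raise DataError(
            f"no samples with >= {min_species} present species; "
            "cannot build a network"
        )
    return counts.loc[keep]


def _log_ratio_variance(frac: np.ndarray) -> np.ndarray:
    """t_ij = var over samples of ln(x_i / x_j) (unbiased, ddof=1)."""
    logf = np.log(frac)
    n, d = logf.shape
    cov = np.cov(logf, rowvar=False, ddof=1)
    var = np.diag(cov)
    return var[:, None] + var[None, :] - 2.0 * cov


def _solve_basis_variances(t: np.ndarray, partners: np.ndarray) -> np.ndarray:
    """Solve the sparsity-approximation linear system for basis variances.

    *partners* is a boolean matrix; ``partners[i, j]`` marks pair (i, j)
    as still included in component i's equation.
    """
    d = t.shape[0]
    a = partners.astype(float)
    np.fill_diagonal(a, 0.0)
    a = a + np.diag(partners.sum(axis=1) - np.diag(partners).astype(float))
    rhs = (t * partners).sum(axis=1)
    w = np.linalg.solve(a, rhs)
    return np.clip(w, 1e-12, None)


def _rho_from_basis(t: np.ndarray, w: np.ndarray) -> np.ndarray:
    rho = (w[:, None] + w[None, :] - t) / (2.0 * np.sqrt(np.outer(w, w)))
    rho = np.clip(rho, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return rho


def _sparcc_single(
    t: np.ndarray,
    n_exclusion_iters: int,
    exclusion_threshold: float,
) -> np.ndarray:
    d = t.shape[0]
    partners = np.ones((d, d), dtype=bool)
    np.fill_diagonal(partners, False)
    w = _solve_basis_variances(t, partners)
    rho = _rho_from_basis(t, w)
    for _ in range(n_exclusion_iters):
        masked = np.abs(np.where(partners, rho, 0.0))
        np.fill_diagonal(masked, 0.0)
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        if masked[i, j] <= exclusion_threshold:
            break
        # keep every component in at least 2 equations
        if partners[i].sum() <= 2 or partners[j].sum() <= 2:
            break
        partners[i, j] = partners[j, i] = False
        w = _solve_basis_variances(t, partners)
        rho = _rho_from_basis(t, w)
    return rho


def sparcc(
    counts: pd.DataFrame,
    n_exclusion_iters: int = 10,
    exclusion_threshold: float = 0.1,
    pseudocount: float = 1.0,
    n_draws: int = 20,
    seed: int | None = None,
) -> pd.DataFrame:
    """Estimate SparCC correlations from a samples x species count matrix.

    ``n_draws`` Dirichlet resamples of the per-sample fractions (prior
    ``counts + pseudocount``) are averaged; ``n_draws=0`` uses the
    deterministic posterior-mean fractions instead, which makes the
    estimate exactly reproducible by the basis-variance linear-system
    oracle.  Returns a symmetric correlation DataFrame with unit
    diagonal, values clipped to [-1, 1].
    """
    n, d = counts.shape
    if d < 4:
        raise DataError("sparcc requires at least 4 species")
    if n < 10:
        raise DataError("sparcc requires at least 10 samples")
    raw = counts.to_numpy(dtype=float) + pseudocount
    rng = np.random.default_rng(seed)
    rhos = []
    draws = max(n_draws, 1)
    for k in range(draws):
        if n_draws == 0:
            frac = raw / raw.sum(axis=1, keepdims=True)
        else:
            frac = rng.standard_gamma(raw)
            frac /= frac.sum(axis=1, keepdims=True)
        logf = np.log(frac)
        flat = np.ptp(logf, axis=0) == 0
        if flat.any():
            bad = counts.columns[flat].tolist()
            raise DataError(f"zero-variance species after pseudocount: {bad[:5]}")
        t = _log_ratio_variance(frac)
        rhos.append(_sparcc_single(t, n_exclusion_iters, exclusion_threshold))
    rho = np.mean(rhos, axis=0)
    rho = (rho + rho.T) / 2.0
    rho = np.clip(rho, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=counts.columns, columns=counts.columns)


def build_network(corr: pd.DataFrame, threshold: float) -> nx.Graph:
    """Threshold a correlation matrix into an undirected network.

    An edge is kept when ``|rho|`` strictly exceeds *threshold*; every
    species stays a node, so isolated nodes are allowed.
    """
    if not (0.0 <= threshold < 1.0):
        raise DataError(f"network threshold {threshold} outside [0, 1)")
    g = nx.Graph(threshold=threshold)
    species = list(corr.columns)
    g.add_nodes_from(species)
    arr = corr.to_numpy()
    iu, ju = np.triu_indices(len(species), k=1)
    for i, j in zip(iu, ju):
        if abs(arr[i, j]) > threshold:
            a, b = sorted((species[i], species[j]))
            g.add_edge(a, b, rho=float(arr[i, j]))
    return g


def intersect_networks(networks: list[nx.Graph]) -> nx.Graph:
    """Edges present (as unordered species pairs) in every input network.

    Edge identity ignores correlation sign and magnitude; the per-network
    correlations are recorded on each surviving edge as ``rho_list``.
    """
    if len(networks) < 2:
        raise DataError("intersect_networks requires at least 2 networks")
    common = set(frozenset(e) for e in networks[0].edges())
    for g in networks[1:]:
        common &= set(frozenset(e) for e in g.edges())
    out = nx.Graph()
    for g in networks:
        out.add_nodes_from(g.nodes())
    for pair in common:
        a, b = sorted(pair)
        out.add_edge(a, b, rho_list=[float(g.edges[a, b]["rho"]) for g in networks])
    return out


def write_edge_list(g: nx.Graph, path: str) -> None:
    rows = []
    for a, b, data in sorted(g.edges(data=True)):
        rho = data.get("rho", data.get("rho_list"))
        if isinstance(rho, list):
            rho = ";".join(f"{x:.6g}" for x in rho)
        else:
            rho = f"{rho:.6g}" if rho is not None else ""
        rows.append((a, b, rho))
    pd.DataFrame(rows, columns=["species_a", "species_b", "rho"]).to_csv(
        path, sep="\t", index=False
    )


def write_graphml(g: nx.Graph, path: str) -> None:
    h = g.copy()
    for _, _, data in h.edges(data=True):
        if "rho_list" in data:
            data["rho_list"] = ";".join(f"{x:.6g}" for x in data["rho_list"])
    nx.write_graphml(h, path)


def write_correlation_tsv(corr: pd.DataFrame, path: str) -> None:
    corr.to_csv(path, sep="\t", index_label="species")
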