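"""Correlation-matrix PCA and the normal / residual parameter split.

The anomaly search space is defined by eigendecomposing the correlation
matrix of the standardized discovery matrix. Components with eigenvalues
above a threshold carry the cohort's typical variation (the "normal
subspace"); each such component is identified with its dominant parameter.
The remaining parameters form the residual subspace, where collective
anomalies that contribute (numerically) nothing to the explained variance
are searched for.

Correlation (not covariance) PCA is forced by the data: parameters mix
counts, percentages, pg/ml and ELISA units, so covariance eigenvalues
would be dominated by scale alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class SubspaceDecomposition:
    parameter_names: tuple[str, ...]
    eigenvalues: np.ndarray          # descending, length p
    loadings: np.ndarray             # (p, p); column j = unit eigenvector j
    variance_fraction: np.ndarray    # eigenvalue / p
    cumulative_fraction: np.ndarray


def standardize(matrix: np.ndarray,
                parameter_names=None) -> np.ndarray:
    """Z-score columns to mean 0 and unit sample (n-1) SD.

    A constant column is an error: it carries no variance information and
    must be dropped by the caller before subspace analysis.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    sd = np.std(x, axis=0, ddof=1)
    if np.any(sd == 0):
        j = int(np.argmin(sd))
        name = parameter_names[j] if parameter_names is not None else f"#{j}"
        raise ValueError(f"constant column {name!r}: drop it before PCA")
    return (x - x.mean(axis=0)) / sd


def pca(z_matrix: np.ndarray, parameter_names=None) -> SubspaceDecomposition:
    """Eigendecompose the sample correlation matrix of a z-scored matrix.

    Eigenvalues are sorted non-increasing; each eigenvector's sign is fixed
    by making its largest-magnitude loading positive, so reports are
    reproducible across linear-algebra backends.
    """
    z = np.asarray(z_matrix, dtype=float)
    n, p = z.shape
    if n < 2:
        raise ValueError("need at least 2 patients")
    if parameter_names is None:
        parameter_names = tuple(f"p{j}" for j in range(p))
    corr = (z.T @ z) / (n - 1)
    corr = (corr + corr.T) / 2.0
    vals, vecs = np.linalg.eigh(corr)
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    vecs = vecs[:, order]
    vals = np.clip(vals, 0.0, None)  # clip numerically negative eigenvalues
    for j in range(p):
        k = int(np.argmax(np.abs(vecs[:, j])))
        if vecs[k, j] < 0:
            vecs[:, j] = -vecs[:, j]
    frac = vals / p
    return SubspaceDecomposition(
        parameter_names=tuple(parameter_names),
        eigenvalues=vals,
        loadings=vecs,
        variance_fraction=frac,
        cumulative_fraction=np.cumsum(frac),
    )


def split_subspaces(decomp: SubspaceDecomposition,
                    eps: float = 0.01) -> tuple[list[str], list[str]]:
    """Partition parameters into normal and residual subspace members.

    Components with eigenvalue > ``eps`` are retained; each is assigned its
    dominant parameter — the largest-|loading| parameter not already
    claimed by a stronger component (greedy, in decreasing-eigenvalue
    order). Retained dominants form the normal subspace; everything else is
    residual, so the residual size is p - n_retained.
    """
    if eps < 0:
        raise ValueError("eps must be non-negative")
    names = decomp.parameter_names
    retained = [j for j, lam in enumerate(decomp.eigenvalues) if lam > eps]
    if not retained:
        raise ValueError("no component exceeds the eigenvalue threshold")
    assigned: list[str] = []
    taken = np.zeros(len(names), dtype=bool)
    for j in retained:
        load = np.abs(decomp.loadings[:, j]).copy()
        load[taken] = -1.0
        k = int(np.argmax(load))
        taken[k] = True
        assigned.append(names[k])
    residual = [nm for nm in names if nm not in set(assigned)]
    return assigned, residual


def variance_explained(decomp: SubspaceDecomposition, k: int) -> float:
    """Cumulative variance fraction of the first k components."""
    p = len(decomp.parameter_names)
    if not 1 <= k <= p:
        raise ValueError(f"k must lie in [1, {p}]")
    return float(decomp.cumulative_fraction[k - 1])


def scree_frame(decomp: SubspaceDecomposition) -> pd.DataFrame:
    return pd.DataFrame({
        "component": np.arange(1, len(decomp.eigenvalues) + 1),
        "eigenvalue": decomp.eigenvalues,
        "cumulative_pct": 100.0 * decomp.cumulative_fraction,
    })
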