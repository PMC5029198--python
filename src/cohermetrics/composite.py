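"""Composite reading measure via correlation-matrix PCA.

Three reading tests (irregular-word reading, speeded sight-word reading,
speeded nonword decoding) are z-transformed and summarised by the first
principal component of their 3x3 correlation matrix.  Working on the
correlation matrix makes the composite invariant to each test's scale, so
raw and standard scores give identical components.  Loadings are reported
in the factor-analytic convention (eigenvector scaled by the square root of
its eigenvalue), so the squared loadings of component one sum to its
eigenvalue and the eigenvalues of the three components sum to three.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CompositeResult", "z_transform", "pca_from_correlation", "pca_composite"]


@dataclass
class CompositeResult:
    """First-principal-component summary of three reading measures."""

    loadings: np.ndarray          # component-1 loadings, all positive
    eigenvalues: np.ndarray       # descending, summing to the variable count
    eigenvectors: np.ndarray      # columns, same order as eigenvalues
    scores: np.ndarray            # per-participant component-1 scores

    @property
    def variance_explained_pct(self) -> float:
        return 100.0 * float(self.eigenvalues[0]) / len(self.eigenvalues)

    def report(self) -> dict:
        return {
            "loadings": [float(x) for x in self.loadings],
            "eigenvalues": [float(x) for x in self.eigenvalues],
            "variance_explained_pct": self.variance_explained_pct,
        }


def z_transform(columns: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Standardise each column to mean 0 and sample (n-1) SD 1."""
    arr = np.asarray(columns, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.shape[0] < 2:
        raise ValueError("need at least two observations")
    sd = arr.std(axis=0, ddof=1)
    if np.any(sd == 0.0):
        raise ValueError("constant column cannot be z-transformed")
    z = (arr - arr.mean(axis=0)) / sd
    if isinstance(columns, pd.DataFrame):
        return pd.DataFrame(z, index=columns.index, columns=columns.columns)
    return z.reshape(np.asarray(columns, dtype=float).shape)


def _fix_sign(vec: np.ndarray) -> np.ndarray:
    """Orient an eigenvector so its loadings are positive.

    For a component with mixed-sign loadings the orientation with a
    positive sum is used; an exactly balanced tie is broken by the sign of
    the first coordinate.
    """
    s = vec.sum()
    if s < 0 or (s == 0 and vec[0] < 0):
        return -vec
    return vec


def pca_from_correlation(corr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of a correlation matrix, eigenvalues descending,
    component-1 orientation fixed to positive loadings."""
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(corr, corr.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    vals, vecs = np.linalg.eigh(corr)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    vecs = np.column_stack([_fix_sign(vecs[:, j]) for j in range(vecs.shape[1])])
    return vals, vecs


def pca_composite(columns: pd.DataFrame | np.ndarray,
                  standardize_scores: bool = True) -> CompositeResult:
    """First-principal-component composite of three reading measures.

    Columns are z-transformed, the 3x3 correlation matrix is
    eigendecomposed, and scores are the projection of the z-scores on the
    first eigenvector.  With ``standardize_scores`` (the default, matching
    the convention of statistics packages that emit unit-variance factor
    scores) the projection is divided by the square root of the first
    eigenvalue so the composite has sample SD 1; otherwise scores stay in
    eigen-projection units with variance equal to that eigenvalue.

    A rank-deficient correlation matrix (perfectly collinear tests) is not
    an error: the decomposition is still returned, with the redundant
    component carrying a (numerically) zero eigenvalue.
    """
    z = np.asarray(z_transform(columns), dtype=float)
    n, p = z.shape
    if p != 3:
        raise ValueError("the composite is defined over exactly three reading measures")
    if n < 4:
        raise ValueError("need at least four participants")
    corr = np.corrcoef(z, rowvar=False)
    vals, vecs = pca_from_correlation(corr)
    vals = np.clip(vals, 0.0, None)  # guard tiny negative rounding
    scores = z @ vecs[:, 0]
    if standardize_scores:
        scores = scores / np.sqrt(vals[0])
    loadings = vecs[:, 0] * np.sqrt(vals[0])
    return CompositeResult(loadings=loadings, eigenvalues=vals,
                           eigenvectors=vecs, scores=scores)
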