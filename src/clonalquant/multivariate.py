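"""PCA of the genotype x trait BLUP matrix.

Traits are standardised across genotypes, so the decomposition is of
the trait correlation matrix and the eigenvalues sum to the number of
traits.  Loadings are reported as trait-component correlations
(eigenvector entries scaled by sqrt(eigenvalue)); component signs are
fixed so the largest-magnitude loading of each component is positive.
With n genotypes at most n - 1 eigenvalues are non-zero, so the code
must (and does) tolerate many more traits than genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["PcaResult", "pca_on_blups", "retain_components", "contribution_rates"]


@dataclass
class PcaResult:
    eigenvalues: np.ndarray
    loadings: pd.DataFrame  # trait x component correlations
    scores: pd.DataFrame  # genotype x component
    contribution_percent: np.ndarray
    cumulative_percent: np.ndarray
    retained: int


def contribution_rates(eigenvalues, n_traits: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-component and cumulative variance-contribution rates (%).

    For correlation-matrix PCA the total variance equals the number of
    traits, so each component contributes 100 * eigenvalue / n_traits.
    """
    if n_traits <= 0:
        raise ValueError("n_traits must be positive")
    lam = np.asarray(eigenvalues, dtype=float)
    if np.any(lam < -1e-10):
        raise ValueError("eigenvalues must be non-negative")
    percent = 100.0 * np.clip(lam, 0.0, None) / n_traits
    return percent, np.cumsum(percent)


def retain_components(result: PcaResult, threshold: float = 1.0) -> int:
    """Kaiser-style retention: count of eigenvalues strictly above threshold."""
    return int(np.sum(result.eigenvalues > threshold))


def pca_on_blups(blups: pd.DataFrame, threshold: float = 1.0) -> PcaResult:
    """Correlation-matrix PCA of a genotype x trait BLUP matrix.

    Each trait column is standardised to zero mean and unit variance
    across genotypes before the eigendecomposition, so the analysis is
    invariant to affine rescaling of any trait.  Requires >= 3
    genotypes; a constant trait column is rejected by name since it
    cannot be standardised.
    """
    if blups.shape[0] < 3:
        raise ValueError("PCA needs >= 3 genotypes")
    values = blups.to_numpy(dtype=float)
    sd = values.std(axis=0, ddof=1)
    constant = np.asarray(blups.columns)[sd == 0]
    if constant.size:
        raise ValueError(f"constant trait column(s): {list(constant)}")
    z = (values - values.mean(axis=0)) / sd
    n, p = z.shape
    corr = (z.T @ z) / (n - 1)

    lam, vec = np.linalg.eigh(corr)
    order = np.argsort(lam)[::-1]
    lam, vec = np.clip(lam[order], 0.0, None), vec[:, order]

    loadings = vec * np.sqrt(lam)[None, :]
    # deterministic sign: largest |loading| per component is positive
    for j in range(p):
        col = loadings[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            loadings[:, j] *= -1
            vec[:, j] *= -1

    comp_names = [f"PC{j + 1}" for j in range(p)]
    scores = z @ vec
    percent, cumulative = contribution_rates(lam, p)
    result = PcaResult(
        eigenvalues=lam,
        loadings=pd.DataFrame(loadings, index=blups.columns, columns=comp_names),
        scores=pd.DataFrame(scores, index=blups.index, columns=comp_names),
        contribution_percent=percent,
        cumulative_percent=cumulative,
        retained=0,
    )
    result.retained = retain_components(result, threshold)
    return result
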