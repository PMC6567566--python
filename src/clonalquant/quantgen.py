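"""Broad-sense heritability, genetic CV and BLUPs for clonal panels.

For asexual organisms only broad-sense heritability is meaningful:
H2 = Vg / VT, with Vg the among-genotype variance component and VT the
total phenotypic variance.  The default VT is the sum of the random
components (genotype + genotype-by-food + residual); the fixed food
share can optionally be folded in since the literature is not uniform
on the denominator.  Evolvability is summarised by the coefficient of
genetic variation CV = 100 * sqrt(Vg) / mean.  Genotype values enter
the multivariate analyses as best linear unbiased predictors (BLUPs),
which shrink raw genotype means towards zero in proportion to how
noisy they are.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from clonalquant.tables import balanced_array, trait_subset
from clonalquant.varcomp import (
    VarianceDecomposition,
    _anova_components,
    _ems_solution,
    _model_arrays,
    ems_decompose,
    reml_decompose,
)

__all__ = [
    "HeritabilityEstimate",
    "broad_sense_h2",
    "genetic_cv",
    "bootstrap_h2_ci",
    "estimate_blups",
    "blup_matrix",
    "summarize_heritability",
]


@dataclass
class HeritabilityEstimate:
    """Broad-sense heritability summary for one trait."""

    trait_name: str
    v_g: float
    v_t: float
    h2: float
    ci_low: float = np.nan
    ci_high: float = np.nan
    cv_percent: float = np.nan
    mu: float = np.nan


def _total_variance(decomp: VarianceDecomposition, vt_definition: str) -> float:
    vt = decomp.sigma2_g + decomp.sigma2_gf + decomp.sigma2_e
    if vt_definition == "with_fixed":
        if decomp.sigma2_f_quasi is None:
            raise ValueError("fixed share unavailable for this decomposition")
        vt += decomp.sigma2_f_quasi
    elif vt_definition != "random":
        raise ValueError("vt_definition must be 'random' or 'with_fixed'")
    return vt


def broad_sense_h2(
    decomp: VarianceDecomposition, vt_definition: str = "random"
) -> HeritabilityEstimate:
    """H2 = Vg / VT from a variance decomposition, clipped to [0, 1].

    A zero total returns H2 = 0 (the degenerate all-constant case).
    """
    v_g = decomp.sigma2_g
    v_t = _total_variance(decomp, vt_definition)
    h2 = float(np.clip(v_g / v_t, 0.0, 1.0)) if v_t > 0 else 0.0
    return HeritabilityEstimate(
        trait_name=decomp.trait_name, v_g=v_g, v_t=v_t, h2=h2
    )


def genetic_cv(v_g: float, mu: float) -> float:
    """Coefficient of genetic variation, 100 * sqrt(Vg) / mu, in percent."""
    if mu <= 0:
        raise ValueError("genetic CV requires a positive trait mean")
    if v_g < 0:
        raise ValueError("genetic variance must be non-negative")
    return 100.0 * float(np.sqrt(v_g)) / float(mu)


def _h2_from_arrays(arr: np.ndarray, vt_definition: str = "random") -> np.ndarray:
    """Vectorised EMS-based H2 for balanced (..., g, f, r) arrays."""
    comp = _anova_components(arr)
    g, f, r = comp["shape"]
    ms = comp["ms"]
    s2_e = np.maximum(ms["residual"], 0.0)
    s2_gf = np.maximum((ms["interaction"] - ms["residual"]) / r, 0.0)
    s2_g = np.maximum((ms["genotype"] - ms["interaction"]) / (r * f), 0.0)
    vt = s2_g + s2_gf + s2_e
    if vt_definition == "with_fixed":
        vt = vt + np.maximum((ms["food"] - ms["interaction"]) / (r * g), 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        h2 = np.where(vt > 0, s2_g / vt, 0.0)
    return np.clip(h2, 0.0, 1.0)


def bootstrap_h2_ci(
    table: pd.DataFrame,
    trait: str,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
    vt_definition: str = "random",
    unit: str = "within_cell",
) -> tuple[float, float]:
    """Percentile bootstrap confidence interval for broad-sense H2.

    With the default ``unit="within_cell"`` individuals are resampled
    with replacement within each genotype x food cell, preserving the
    design structure; H2 is recomputed per replicate via the moment
    decomposition.  This conditions on the realised genotype effects,
    so the interval reflects measurement replication only and can be
    anti-conservative about the genotype-sampling uncertainty that
    dominates H2 with few genotypes.  ``unit="genotype"`` additionally
    resamples whole genotypes with replacement (a clustered bootstrap)
    to fold that level in.  Deterministic for a fixed seed.
    """
    if n_boot < 200:
        raise ValueError("n_boot must be >= 200 for a stable percentile interval")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    if unit not in ("within_cell", "genotype"):
        raise ValueError("unit must be 'within_cell' or 'genotype'")
    arr, genotypes, foods = balanced_array(table, trait)
    g, f, r = arr.shape
    if r < 2:
        raise ValueError("every genotype x food cell needs >= 2 individuals")
    rng = np.random.default_rng(seed)
    if unit == "genotype":
        gidx = rng.integers(0, g, size=(n_boot, g))
        gi = gidx[:, :, None, None]
    else:
        gi = np.broadcast_to(np.arange(g)[None, :, None, None], (n_boot, g, 1, 1))
    idx = rng.integers(0, r, size=(n_boot, g, f, r))
    fi = np.arange(f)[None, None, :, None]
    h2 = _h2_from_arrays(arr[gi, fi, idx], vt_definition)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(h2, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def estimate_blups(
    table: pd.DataFrame,
    trait: str,
    decomp: VarianceDecomposition | None = None,
    method: str = "reml",
) -> pd.Series:
    """Empirical BLUPs of the genotype random effects for one trait.

    The prediction is u_hat = sigma2_g * Zg' V^{-1} (y - X beta_hat)
    with the variance components plugged in from ``decomp`` (estimated
    by REML, or EMS on balanced data, when not supplied) and beta_hat
    the GLS fixed-effect estimate.  When sigma2_g = 0 every BLUP is
    exactly 0 — with no genetic variance there is nothing to predict.
    Shrinkage guarantees |BLUP| <= |raw genotype-mean deviation|.
    """
    sub = trait_subset(table, trait)
    y, X, g_codes, cell_codes, genotypes, foods = _model_arrays(sub)
    if decomp is None:
        decomp = (
            reml_decompose(table, trait)
            if method == "reml"
            else ems_decompose(table, trait)
        )
    s2g, s2gf, s2e = decomp.sigma2_g, decomp.sigma2_gf, decomp.sigma2_e
    if s2g == 0:
        return pd.Series(0.0, index=genotypes, name=trait)
    if s2e == 0:
        # near-deterministic data: ridge keeps V invertible
        s2e = 1e-10 * max(s2g + s2gf, 1.0)
    n = len(y)
    V = s2e * np.eye(n)
    V += s2g * (g_codes[:, None] == g_codes[None, :])
    V += s2gf * (cell_codes[:, None] == cell_codes[None, :])
    Vinv_X = np.linalg.solve(V, X)
    beta = np.linalg.solve(X.T @ Vinv_X, Vinv_X.T @ y)
    resid_w = np.linalg.solve(V, y - X @ beta)
    blups = np.array(
        [s2g * resid_w[g_codes == i].sum() for i in range(len(genotypes))]
    )
    return pd.Series(blups, index=genotypes, name=trait)


def blup_matrix(
    table: pd.DataFrame, traits: list[str] | None = None, method: str = "reml"
) -> pd.DataFrame:
    """Genotype x trait matrix of BLUP effects."""
    if traits is None:
        traits = sorted(table["trait"].unique())
    cols = {t: estimate_blups(table, t, method=method) for t in traits}
    return pd.DataFrame(cols)


def summarize_heritability(estimates) -> tuple[float, float, float]:
    """Arithmetic mean and range of a collection of H2 values.

    Accepts floats or :class:`HeritabilityEstimate` objects.
    """
    values = [
        e.h2 if isinstance(e, HeritabilityEstimate) else float(e) for e in estimates
    ]
    if not values:
        raise ValueError("need at least one heritability estimate")
    return float(np.mean(values)), float(min(values)), float(max(values))
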