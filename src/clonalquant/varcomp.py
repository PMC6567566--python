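"""Two-way mixed-model variance decomposition for clonal designs.

The model for one trait is

    y_{gfk} = mu + alpha_f + u_g + w_{gf} + e_{gfk}

with food level f a fixed factor and genotype g and the genotype-by-food
interaction random, u_g ~ N(0, sigma2_g), w_{gf} ~ N(0, sigma2_gf),
e ~ N(0, sigma2_e).  Two estimation routes are provided:

* :func:`ems_decompose` — method-of-moments solution of the
  expected-mean-squares equations (balanced designs only), with the
  associated mixed-model F-tests from :func:`anova_two_way`;
* :func:`reml_decompose` — restricted maximum likelihood, which
  tolerates unbalanced replication and constrains components to be
  non-negative.

On balanced data with all solutions interior the two routes coincide.
Negative moment estimates are truncated to zero, mirroring the exact
0.00 entries conventional in published variance-component tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from clonalquant.tables import balanced_array, trait_subset

__all__ = [
    "VarianceDecomposition",
    "anova_two_way",
    "ems_decompose",
    "reml_decompose",
    "variance_percent",
]


@dataclass
class VarianceDecomposition:
    """Estimated variance components for one trait.

    ``f_tests`` is the mixed-model ANOVA table (None when the design is
    unbalanced and only REML ran).  ``sigma2_f_quasi`` is an as-if-random
    moment estimate for the fixed food factor, kept only so the fixed
    share can optionally be folded into percent-of-variance reporting.
    """

    trait_name: str
    sigma2_g: float
    sigma2_gf: float
    sigma2_e: float
    method: str
    n_genotypes: int
    n_foods: int
    f_tests: pd.DataFrame | None = None
    sigma2_f_quasi: float | None = None
    converged: bool = True
    loglik: float | None = None

    def __post_init__(self):
        if min(self.sigma2_g, self.sigma2_gf, self.sigma2_e) < 0:
            raise ValueError("variance components must be non-negative")


def _anova_components(arr: np.ndarray) -> dict:
    """Sums of squares / mean squares for a balanced (..., g, f, r) array.

    Vectorised over any leading batch dimensions, which keeps bootstrap
    and simulation loops cheap.
    """
    g, f, r = arr.shape[-3:]
    cell = arr.mean(axis=-1)
    mg = arr.mean(axis=(-2, -1))
    mf = arr.mean(axis=(-3, -1))
    grand = arr.mean(axis=(-3, -2, -1))
    grand_e = grand[..., None]
    ss_g = f * r * ((mg - grand_e) ** 2).sum(axis=-1)
    ss_f = g * r * ((mf - grand_e) ** 2).sum(axis=-1)
    inter = cell - mg[..., :, None] - mf[..., None, :] + grand[..., None, None]
    ss_gf = r * (inter**2).sum(axis=(-2, -1))
    ss_e = ((arr - cell[..., None]) ** 2).sum(axis=(-3, -2, -1))
    df = {
        "genotype": g - 1,
        "food": f - 1,
        "interaction": (g - 1) * (f - 1),
        "residual": g * f * (r - 1),
    }
    ms = {
        "genotype": ss_g / df["genotype"],
        "food": ss_f / df["food"],
        "interaction": ss_gf / df["interaction"],
        "residual": ss_e / df["residual"] if df["residual"] > 0 else np.nan,
    }
    return {
        "ss": {"genotype": ss_g, "food": ss_f, "interaction": ss_gf, "residual": ss_e},
        "df": df,
        "ms": ms,
        "shape": (g, f, r),
    }


def _f_table(comp: dict, convention: str = "unrestricted") -> pd.DataFrame:
    """Mixed-model F-tests from balanced ANOVA components.

    Food (fixed) is always tested over the interaction mean square; the
    interaction over the residual.  The genotype (random) denominator is
    the interaction MS under the unrestricted-model convention and the
    residual MS under the restricted one.
    """
    ms, df = comp["ms"], comp["df"]
    g_den = "interaction" if convention == "unrestricted" else "residual"
    rows = []
    for term, den in (("genotype", g_den), ("food", "interaction"),
                      ("interaction", "residual")):
        with np.errstate(invalid="ignore", divide="ignore"):
            f_stat = ms[term] / ms[den]  # nan for all-constant data
        p = stats.f.sf(f_stat, df[term], df[den])
        rows.append(
            {
                "term": term,
                "ss": float(comp["ss"][term]),
                "df": df[term],
                "ms": float(ms[term]),
                "df_denom": df[den],
                "F": float(f_stat),
                "p": float(p),
            }
        )
    rows.append(
        {
            "term": "residual",
            "ss": float(comp["ss"]["residual"]),
            "df": df["residual"],
            "ms": float(ms["residual"]),
            "df_denom": np.nan,
            "F": np.nan,
            "p": np.nan,
        }
    )
    return pd.DataFrame(rows).set_index("term")


def anova_two_way(
    table: pd.DataFrame, trait: str, convention: str = "unrestricted"
) -> pd.DataFrame:
    """Two-way mixed-model ANOVA (genotype random, food fixed) for one trait.

    Requires a balanced design with >= 2 genotypes, >= 2 food levels and
    >= 2 replicates per cell.  Returns the ANOVA table with sums of
    squares, mean squares, F ratios against the mixed-model error terms
    and p-values from the F distribution.
    """
    arr, genotypes, foods = balanced_array(table, trait)
    g, f, r = arr.shape
    if g < 2 or f < 2:
        raise ValueError("need >= 2 genotypes and >= 2 food levels")
    if r < 2:
        raise ValueError("need >= 2 replicates per cell")
    return _f_table(_anova_components(arr), convention)


def _ems_solution(comp: dict, convention: str = "unrestricted") -> tuple:
    g, f, r = comp["shape"]
    ms = comp["ms"]
    s2_e = float(ms["residual"])
    s2_gf = float((ms["interaction"] - ms["residual"]) / r)
    if convention == "unrestricted":
        s2_g = float((ms["genotype"] - ms["interaction"]) / (r * f))
    else:
        s2_g = float((ms["genotype"] - ms["residual"]) / (r * f))
    s2_f_quasi = float((ms["food"] - ms["interaction"]) / (r * g))
    return (
        max(s2_g, 0.0),
        max(s2_gf, 0.0),
        max(s2_e, 0.0),
        max(s2_f_quasi, 0.0),
    )


def ems_decompose(
    table: pd.DataFrame, trait: str, convention: str = "unrestricted"
) -> VarianceDecomposition:
    """Moment estimates of the variance components from the EMS equations.

    For the unrestricted mixed model:

        sigma2_e  = MS_error
        sigma2_gf = (MS_GxF - MS_error) / r
        sigma2_g  = (MS_G - MS_GxF) / (r * f)

    Negative solutions are truncated to zero.  Balanced designs only;
    unbalanced input raises with a pointer to :func:`reml_decompose`.
    """
    arr, genotypes, foods = balanced_array(table, trait)
    g, f, r = arr.shape
    if g < 2 or f < 2 or r < 2:
        raise ValueError("need >= 2 genotypes, food levels and replicates")
    comp = _anova_components(arr)
    s2_g, s2_gf, s2_e, s2_f = _ems_solution(comp, convention)
    return VarianceDecomposition(
        trait_name=trait,
        sigma2_g=s2_g,
        sigma2_gf=s2_gf,
        sigma2_e=s2_e,
        method="ems",
        n_genotypes=g,
        n_foods=f,
        f_tests=_f_table(comp, convention),
        sigma2_f_quasi=s2_f,
    )


def _model_arrays(sub: pd.DataFrame):
    """Response, fixed-effect design and random-factor codes for one trait."""
    y = sub["value"].to_numpy(dtype=float)
    genotypes = sorted(sub["genotype"].unique())
    foods = sorted(sub["food"].unique())
    g_codes = sub["genotype"].map({g: i for i, g in enumerate(genotypes)}).to_numpy()
    f_codes = sub["food"].map({f: i for i, f in enumerate(foods)}).to_numpy()
    cell_codes = g_codes * len(foods) + f_codes
    X = np.ones((len(y), len(foods)))
    for j in range(1, len(foods)):
        X[:, j] = (f_codes == j).astype(float)
    return y, X, g_codes, cell_codes, genotypes, foods


def _reml_neg2_profile(gamma, y, X, g_codes, cell_codes):
    """-2 restricted log-likelihood profiled over sigma2_e.

    gamma = (sigma2_g, sigma2_gf) / sigma2_e.  H = I + g_g A + g_gf B
    where A and B are the same-genotype and same-cell indicators.
    """
    n, p = X.shape
    gam_g, gam_gf = gamma
    H = np.eye(n)
    H += gam_g * (g_codes[:, None] == g_codes[None, :])
    H += gam_gf * (cell_codes[:, None] == cell_codes[None, :])
    try:
        L = np.linalg.cholesky(H)
    except np.linalg.LinAlgError:
        return np.inf
    logdet_H = 2.0 * np.log(np.diag(L)).sum()
    Xi = np.linalg.solve(L, X)
    yi = np.linalg.solve(L, y)
    XtHX = Xi.T @ Xi
    sign, logdet_XtHX = np.linalg.slogdet(XtHX)
    if sign <= 0:
        return np.inf
    beta = np.linalg.solve(XtHX, Xi.T @ yi)
    resid = yi - Xi @ beta
    q = float(resid @ resid)
    if q <= 0:
        return np.inf
    s2e = q / (n - p)
    return (n - p) * np.log(s2e) + logdet_H + logdet_XtHX + (n - p)


def reml_decompose(
    table: pd.DataFrame, trait: str, convention: str = "unrestricted"
) -> VarianceDecomposition:
    """Restricted-maximum-likelihood variance components for one trait.

    The restricted likelihood is profiled over the residual variance and
    maximised over the variance ratios (sigma2_g/sigma2_e,
    sigma2_gf/sigma2_e) with a bounded quasi-Newton optimiser,
    multi-started from the moment solution and fixed fallbacks.
    Components at the zero boundary are legitimate estimates, not
    errors.  Tolerates unbalanced replication; F-tests are attached only
    when the design is balanced.
    """
    sub = trait_subset(table, trait)
    y, X, g_codes, cell_codes, genotypes, foods = _model_arrays(sub)
    if len(genotypes) < 2:
        raise ValueError("need >= 2 genotypes")
    n, p = X.shape
    if n - p < 2:
        raise ValueError("not enough residual degrees of freedom")

    var_y = float(np.var(y, ddof=1))
    if var_y == 0:
        return VarianceDecomposition(
            trait_name=trait, sigma2_g=0.0, sigma2_gf=0.0, sigma2_e=0.0,
            method="reml", n_genotypes=len(genotypes), n_foods=len(foods),
        )

    starts = [(0.5, 0.5), (0.05, 0.05), (5.0, 0.5), (0.0, 0.0)]
    f_tests = None
    s2_f_quasi = None
    try:
        arr, _, _ = balanced_array(table, trait)
        if arr.shape[1] >= 2 and arr.shape[2] >= 2:
            comp = _anova_components(arr)
            f_tests = _f_table(comp, convention)
            s2_g0, s2_gf0, s2_e0, s2_f_quasi = _ems_solution(comp, convention)
            if s2_e0 > 0:
                starts.insert(0, (s2_g0 / s2_e0, s2_gf0 / s2_e0))
    except ValueError:
        pass

    # one food level: cell == genotype, so the interaction is confounded
    # with the genotype effect and is pinned at zero
    gf_bound = (0.0, 0.0) if len(foods) < 2 else (0.0, 1e8)
    args = (y, X, g_codes, cell_codes)
    best = None
    for start in starts:
        x0 = np.asarray(start, dtype=float)
        x0[1] = min(x0[1], gf_bound[1])
        res = optimize.minimize(
            _reml_neg2_profile,
            x0=x0,
            args=args,
            method="L-BFGS-B",
            bounds=[(0.0, 1e8), gf_bound],
        )
        if best is None or res.fun < best.fun:
            best = res
    gam_g, gam_gf = best.x
    # recompute profiled residual variance at the optimum
    H = np.eye(n)
    H += gam_g * (g_codes[:, None] == g_codes[None, :])
    H += gam_gf * (cell_codes[:, None] == cell_codes[None, :])
    L = np.linalg.cholesky(H)
    Xi = np.linalg.solve(L, X)
    yi = np.linalg.solve(L, y)
    beta = np.linalg.solve(Xi.T @ Xi, Xi.T @ yi)
    resid = yi - Xi @ beta
    s2e = float(resid @ resid) / (n - p)
    return VarianceDecomposition(
        trait_name=trait,
        sigma2_g=float(gam_g * s2e),
        sigma2_gf=float(gam_gf * s2e),
        sigma2_e=float(s2e),
        method="reml",
        n_genotypes=len(genotypes),
        n_foods=len(foods),
        f_tests=f_tests,
        sigma2_f_quasi=s2_f_quasi,
        converged=bool(best.success),
        loglik=-0.5 * float(best.fun),
    )


def variance_percent(
    decomp: VarianceDecomposition, include_fixed: bool = False
) -> dict[str, float]:
    """Percent of variance attributed to each term.

    By default the denominator is the sum of the random components
    (genotype + interaction + residual).  With ``include_fixed`` the
    fixed food factor is folded in through its as-if-random moment
    estimate — a reporting convention for tables that print a food
    share, not a true variance component.  An all-zero total yields all
    zeros by convention.
    """
    parts = {
        "genotype": decomp.sigma2_g,
        "interaction": decomp.sigma2_gf,
        "residual": decomp.sigma2_e,
    }
    if include_fixed:
        if decomp.sigma2_f_quasi is None:
            raise ValueError(
                "fixed-effect share unavailable (no balanced ANOVA attached)"
            )
        parts["food"] = decomp.sigma2_f_quasi
    total = sum(parts.values())
    if total == 0:
        return {k: 0.0 for k in parts}
    return {k: 100.0 * v / total for k, v in parts.items()}
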