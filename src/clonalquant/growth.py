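"""Von Bertalanffy growth fitting and life-history trait extraction.

Body-length trajectories are summarised by the von Bertalanffy curve

    L_t = L_inf * (1 - exp(-k * (t - t0)))

where L_inf is the asymptotic body length (mm), k the growth
coefficient (per day) and t0 the hypothetical age at zero length
(days).  Fits are per individual by default, preserving replication for
the downstream variance decomposition.  The same trajectories carry egg
counts and moult events, from which the life-history traits are read
off: maturation is the first age at which eggs appear in the brood
pouch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from clonalquant.synthetic_data import von_bertalanffy_length

__all__ = [
    "GrowthFit",
    "fit_von_bertalanffy",
    "derive_life_history",
    "traits_from_trajectories",
]


@dataclass
class GrowthFit:
    """Result of one von Bertalanffy fit."""

    l_inf: float
    k: float
    t0: float
    rss: float
    converged: bool

    def predict(self, t) -> np.ndarray:
        return von_bertalanffy_length(t, self.l_inf, self.k, self.t0)


def _start_values(t: np.ndarray, length: np.ndarray) -> list[tuple]:
    """Candidate (L_inf, k, t0) starts.

    The primary start takes L_inf slightly above the largest observed
    length and gets k, t0 from the log-linearisation
    log(1 - L/L_inf) = -k t + k t0.
    """
    l_max = float(length.max())
    starts = []
    l0 = 1.05 * l_max
    frac = 1.0 - np.clip(length / l0, 1e-9, 1 - 1e-9)
    slope, intercept = np.polyfit(t, np.log(frac), 1)
    if slope < 0:
        k0 = -float(slope)
        starts.append((l0, k0, float(intercept / k0)))
    starts.append((l0, 0.2, 0.0))
    starts.append((2.0 * l_max, 0.05, 0.0))
    return starts


def fit_von_bertalanffy(obs: pd.DataFrame | None = None, *, t=None, length=None) -> GrowthFit:
    """Nonlinear least-squares fit of the von Bertalanffy curve.

    Accepts either a trajectory frame with ``age_d`` and
    ``body_length_mm`` columns or explicit ``t``/``length`` arrays.
    Requires >= 4 observations over >= 3 distinct ages.  Multi-started;
    a trajectory on which no start converges (e.g. constant length, for
    which k is unidentifiable) is returned with ``converged=False`` and
    NaN parameters.

    Bounds stabilise short trajectories: L_inf in (0, 3 * max length],
    k in (0, 5].
    """
    if obs is not None:
        t = obs["age_d"].to_numpy(dtype=float)
        length = obs["body_length_mm"].to_numpy(dtype=float)
    t = np.asarray(t, dtype=float)
    length = np.asarray(length, dtype=float)
    if t.size < 4 or np.unique(t).size < 3:
        raise ValueError("need >= 4 observations spanning >= 3 distinct ages")

    l_max = float(length.max())
    if l_max <= 0 or np.ptp(length) == 0:
        return GrowthFit(np.nan, np.nan, np.nan, np.nan, converged=False)

    bounds = ([1e-9, 1e-9, -np.inf], [3.0 * l_max, 5.0, np.inf])
    best = None
    for start in _start_values(t, length):
        p0 = np.clip(start, bounds[0], bounds[1])
        try:
            popt, _ = curve_fit(
                von_bertalanffy_length, t, length, p0=p0, bounds=bounds, maxfev=20000
            )
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((length - von_bertalanffy_length(t, *popt)) ** 2))
        if best is None or rss < best[1]:
            best = (popt, rss)
    if best is None:
        return GrowthFit(np.nan, np.nan, np.nan, np.nan, converged=False)
    (l_inf, k, t0), rss = best
    return GrowthFit(float(l_inf), float(k), float(t0), rss, converged=True)


def derive_life_history(obs: pd.DataFrame) -> dict:
    """Life-history and morphology traits from one individual's trajectory.

    maturation age
        first age with a positive egg count (eggs first visible in the
        brood pouch); absent when no eggs are ever observed, in which
        case the maturation-linked traits are NaN but the rest are still
        returned.
    maturation instar
        number of moults before maturation + 1.
    intermoult durations
        mean gap between successive moult events before and after
        maturation.
    clutch summaries
        mean egg number and mean neonate size over the first three
        clutches (clutch boundaries = adult moults).
    relative tail-spine length
        tail-spine length / body length at maturation (first adult
        instar); dimensionless.
    """
    obs = obs.sort_values("age_d")
    ages = obs["age_d"].to_numpy(dtype=float)
    if np.any(np.diff(ages) <= 0):
        raise ValueError("ages must be strictly increasing per individual")
    lengths = obs["body_length_mm"].to_numpy(dtype=float)
    eggs = obs["egg_count"].to_numpy() if "egg_count" in obs else np.zeros(len(obs))
    moults = obs["moult"].to_numpy() if "moult" in obs else np.zeros(len(obs))

    out: dict = {}
    mature_idx = np.nonzero(eggs > 0)[0]
    if mature_idx.size == 0:
        out.update(
            maturation_age=np.nan,
            maturation_instar=np.nan,
            maturation_body_length=np.nan,
            relative_tail_spine=np.nan,
            intermoult_pre_maturation=np.nan,
            intermoult_post_maturation=np.nan,
            mean_egg_number=np.nan,
            mean_neonate_size=np.nan,
        )
    else:
        i_mat = mature_idx[0]
        mat_age = float(ages[i_mat])
        out["maturation_age"] = mat_age
        out["maturation_instar"] = float(moults[:i_mat].sum()) + 1.0
        out["maturation_body_length"] = float(lengths[i_mat])
        if "tail_spine_mm" in obs:
            tail = obs["tail_spine_mm"].to_numpy(dtype=float)[i_mat]
            out["relative_tail_spine"] = float(tail) / float(lengths[i_mat])
        else:
            out["relative_tail_spine"] = np.nan

        # expand per-day moult counts into event times for gap statistics
        moult_ages = np.repeat(ages, moults.astype(int))
        pre = moult_ages[moult_ages <= mat_age]
        post = moult_ages[moult_ages > mat_age]
        out["intermoult_pre_maturation"] = (
            float(np.diff(pre).mean()) if pre.size >= 2 else np.nan
        )
        out["intermoult_post_maturation"] = (
            float(np.diff(post).mean()) if post.size >= 2 else np.nan
        )

        # clutches: egg counts per adult instar, delimited by adult moults
        boundaries = np.concatenate([[mat_age], post, [ages[-1] + 1]])
        clutch_sizes, neonate_sizes = [], []
        for lo, hi in zip(boundaries[:-1], boundaries[1:]):
            in_instar = (ages >= lo) & (ages < hi)
            if not in_instar.any():
                continue
            clutch = eggs[in_instar].max()
            if clutch > 0:
                clutch_sizes.append(float(clutch))
                if "neonate_size_mm" in obs:
                    sizes = obs.loc[in_instar, "neonate_size_mm"].dropna()
                    if len(sizes):
                        neonate_sizes.append(float(sizes.mean()))
            if len(clutch_sizes) == 3:
                break
        out["mean_egg_number"] = (
            float(np.mean(clutch_sizes)) if clutch_sizes else np.nan
        )
        out["mean_neonate_size"] = (
            float(np.mean(neonate_sizes)) if neonate_sizes else np.nan
        )

    day5 = obs.loc[obs["age_d"] == 5]
    out["body_length_day5"] = (
        float(day5["body_length_mm"].iloc[0]) if len(day5) else np.nan
    )
    return out


def traits_from_trajectories(
    traj: pd.DataFrame, fit_growth: bool = True
) -> pd.DataFrame:
    """Per-individual trait table (long format) from a trajectory table.

    Extracts the life-history record of every individual and, when
    ``fit_growth`` is set, adds the fitted asymptotic length ``l_inf``
    and growth coefficient ``k``.  Output columns match the phenotype
    table contract (individual, genotype, food, trait, value);
    non-finite trait values and failed fits are dropped.
    """
    records = []
    for ind, sub in traj.groupby("individual", sort=False):
        rec = derive_life_history(sub)
        if fit_growth:
            fit = fit_von_bertalanffy(sub)
            rec["l_inf"] = fit.l_inf if fit.converged else np.nan
            rec["k"] = fit.k if fit.converged else np.nan
        for trait, value in rec.items():
            records.append(
                {
                    "individual": ind,
                    "genotype": sub["genotype"].iloc[0],
                    "food": sub["food"].iloc[0],
                    "trait": trait,
                    "value": value,
                }
            )
    out = pd.DataFrame(records)
    return out.loc[np.isfinite(out["value"].to_numpy(dtype=float))].reset_index(
        drop=True
    )
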