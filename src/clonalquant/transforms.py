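"""Variance-stabilising transforms applied before ANOVA.

Two transforms cover the trait list of the clonal *Daphnia* assay:
a base-10 log for right-skewed positive traits (enzyme activities,
maturation age, egg number, early body length) and a rank-based
two-step normalisation for traits whose distribution resists a simple
log (intermoult duration before maturation).  The two-step transform
maps fractional ranks through the standard-normal inverse CDF, yielding
an order-preserving, approximately normal score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from clonalquant.tables import validate_phenotype_table

#: Default per-trait transform assignments for the five-clone assay.
DEFAULT_TRANSFORMS = {
    "beta_glucosidase": "log",
    "alkaline_phosphatase": "log",
    "arginine_aminopeptidase": "log",
    "maturation_age": "log",
    "mean_egg_number": "log",
    "body_length_day5": "log",
    "intermoult_pre_maturation": "two_step",
}

_METHODS = ("log", "two_step", "none")


@dataclass(frozen=True)
class TransformSpec:
    trait_name: str
    method: str = "none"

    def __post_init__(self):
        if self.method not in _METHODS:
            raise ValueError(f"unknown transform {self.method!r}; use one of {_METHODS}")


def log_transform(values) -> np.ndarray:
    """Elementwise base-10 logarithm of strictly positive values."""
    arr = np.asarray(values, dtype=float)
    bad = np.nonzero(~(arr > 0))[0]
    if bad.size:
        raise ValueError(
            f"log transform requires positive values; offending row index {bad[0]}"
        )
    return np.log10(arr)


def two_step_transform(values) -> np.ndarray:
    """Rank-based inverse-normal transform.

    Step 1 maps each value to its fractional rank (rank - 0.5)/n, using
    mean ranks for ties, so that every rank lands strictly inside (0, 1)
    and the extremes stay finite.  Step 2 applies the standard-normal
    inverse CDF.  The output preserves order and is approximately
    standard normal for continuous inputs.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 3:
        raise ValueError("two-step transform needs at least 3 values")
    if np.ptp(arr) == 0:
        raise ValueError("two-step transform undefined for constant input")
    ranks = stats.rankdata(arr, method="average")
    frac = (ranks - 0.5) / arr.size
    return stats.norm.ppf(frac)


def apply_transforms(
    table: pd.DataFrame, specs: dict[str, str] | None = None
) -> pd.DataFrame:
    """Return a copy of a phenotype table with per-trait transforms applied.

    ``specs`` maps trait name to method ('log', 'two_step' or 'none');
    traits not listed are left untouched.  Defaults to
    :data:`DEFAULT_TRANSFORMS`.  The two-step transform is applied per
    trait across all individuals (both food levels pooled), since it is
    a property of the trait's full distribution.
    """
    validate_phenotype_table(table)
    if specs is None:
        specs = DEFAULT_TRANSFORMS
    out = table.copy()
    for trait, method in specs.items():
        mask = out["trait"] == trait
        if not mask.any():
            continue
        vals = out.loc[mask, "value"].to_numpy(dtype=float)
        if method == "log":
            try:
                out.loc[mask, "value"] = log_transform(vals)
            except ValueError as err:
                raise ValueError(f"trait {trait!r}: {err}") from None
        elif method == "two_step":
            out.loc[mask, "value"] = two_step_transform(vals)
        elif method != "none":
            raise ValueError(f"unknown transform {method!r} for trait {trait!r}")
    return out
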