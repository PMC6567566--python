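"""Phenotype-table conventions shared across modules.

A *phenotype table* is a long-format :class:`pandas.DataFrame` with one
row per individual per trait and the columns

    individual  genotype  food  trait  value

``genotype`` and ``food`` are treated as categorical labels; ``value``
is the trait measurement on whatever scale the caller chose (raw or
transformed).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

PHENOTYPE_COLUMNS = ("individual", "genotype", "food", "trait", "value")


def validate_phenotype_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format phenotype-table contract and return the table."""
    missing = [c for c in PHENOTYPE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"phenotype table missing columns: {missing}")
    if table.empty:
        raise ValueError("phenotype table is empty")
    return table


def trait_subset(table: pd.DataFrame, trait: str) -> pd.DataFrame:
    """Rows of one trait, with non-finite values rejected."""
    validate_phenotype_table(table)
    sub = table.loc[table["trait"] == trait]
    if sub.empty:
        raise ValueError(f"trait {trait!r} not present in table")
    if not np.isfinite(sub["value"].to_numpy(dtype=float)).all():
        raise ValueError(f"trait {trait!r} contains non-finite values")
    return sub


def balanced_array(
    table: pd.DataFrame, trait: str
) -> tuple[np.ndarray, list, list]:
    """Reshape one trait into a (genotype, food, replicate) array.

    Returns ``(values, genotype_labels, food_labels)``.  Raises
    ``ValueError`` if any genotype x food cell is empty or cell sizes
    are unequal (the balanced-design requirement of the moment-based
    decomposition).
    """
    sub = trait_subset(table, trait)
    genotypes = sorted(sub["genotype"].unique())
    foods = sorted(sub["food"].unique())
    counts = sub.groupby(["genotype", "food"], observed=True).size()
    if len(counts) != len(genotypes) * len(foods):
        raise ValueError("design has empty genotype x food cells")
    if counts.nunique() != 1:
        raise ValueError(
            "unbalanced design (unequal cell sizes); use reml_decompose"
        )
    r = int(counts.iloc[0])
    arr = np.empty((len(genotypes), len(foods), r), dtype=float)
    grouped = sub.groupby(["genotype", "food"], observed=True)["value"]
    for (g, f), vals in grouped:
        arr[genotypes.index(g), foods.index(f), :] = vals.to_numpy(dtype=float)
    return arr, genotypes, foods
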