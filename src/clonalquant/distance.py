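"""Distance matrices and the Mantel test.

Phenotypic divergence between clonal genotypes is measured as the
standardised Euclidean distance over BLUP trait values; genomic
divergence as the uncorrected p-distance (fraction of compared sites
that differ).  The two are related by a Mantel permutation test whose
null distribution relabels the genotypes of one matrix.  At the scale
of a five-clone panel all 5! = 120 relabelings can be enumerated, which
removes Monte-Carlo noise entirely; enumeration is the default up to
n = 7 genotypes.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DistanceMatrix",
    "MantelResult",
    "phenotypic_distance",
    "p_distance",
    "mantel_test",
    "read_snp_tsv",
    "read_fasta_matrix",
]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with genotype labels."""

    labels: tuple
    values: np.ndarray
    kind: str = "phenotypic"  # or "genetic"
    trait_scope: str = "overall"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.labels):
            raise ValueError("values must be square and match the labels")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix must have a zero diagonal")
        if np.any(v < -1e-12):
            raise ValueError("distances must be non-negative")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path, kind: str = "phenotypic", trait_scope: str = "overall"):
        frame = pd.read_csv(path, index_col=0)
        return cls(tuple(frame.index), frame.to_numpy(dtype=float), kind, trait_scope)

    def to_phylip(self, path) -> None:
        """Square PHYLIP distance format."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for lab, row in zip(self.labels, self.values):
                cells = " ".join(f"{x:.6f}" for x in row)
                fh.write(f"{str(lab)[:10]:<10} {cells}\n")


@dataclass
class MantelResult:
    r: float
    p: float
    n_permutations: int
    exhaustive: bool
    tail: str = "greater"


def phenotypic_distance(
    blups: pd.DataFrame, scope: list[str] | None = None, name: str = "overall"
) -> DistanceMatrix:
    """Standardised Euclidean distance between genotypes over BLUPs.

    Each trait column (restricted to ``scope`` when given) is divided by
    its standard deviation across genotypes before the Euclidean
    distance is taken, so every trait contributes on a common scale.
    Needs >= 3 genotypes: with two, standardisation collapses every
    trait to the same +/- pair and the distance is uninformative.
    """
    cols = list(scope) if scope is not None else list(blups.columns)
    if not cols:
        raise ValueError("trait scope is empty")
    missing = [c for c in cols if c not in blups.columns]
    if missing:
        raise ValueError(f"traits not in BLUP matrix: {missing}")
    if blups.shape[0] < 3:
        raise ValueError("standardised distance needs >= 3 genotypes")
    values = blups[cols].to_numpy(dtype=float)
    sd = values.std(axis=0, ddof=1)
    zero = [c for c, s in zip(cols, sd) if s == 0]
    if zero:
        raise ValueError(f"zero-variance trait(s) in scope: {zero}")
    z = values / sd
    diff = z[:, None, :] - z[None, :, :]
    d = np.sqrt((diff**2).sum(axis=-1))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(tuple(blups.index), d, "phenotypic", name)


def p_distance(matrix: pd.DataFrame) -> DistanceMatrix:
    """Uncorrected p-distance between rows of a clone x site matrix.

    Entries may be any hashable site states (0/1 integers, bases, ...);
    NaN marks missing data.  For each pair, sites missing in either
    member are excluded from that pair's denominator.  A pair with zero
    comparable sites is an error.
    """
    if matrix.shape[0] < 2:
        raise ValueError("need >= 2 clones")
    values = matrix.to_numpy()
    labels = tuple(matrix.index)
    if values.dtype.kind in "fiu":
        arr = values.astype(float)
        valid = np.isfinite(arr)
        diff = arr[:, None, :] != arr[None, :, :]
    else:
        s = np.char.upper(values.astype(str))
        valid = ~np.isin(s, ("NAN", "N", "-", "?", ""))
        diff = s[:, None, :] != s[None, :, :]
    both = valid[:, None, :] & valid[None, :, :]
    n_comp = both.sum(axis=-1)
    n = len(labels)
    off = ~np.eye(n, dtype=bool)
    if np.any(n_comp[off] == 0):
        i, j = np.argwhere(off & (n_comp == 0))[0]
        raise ValueError(f"no comparable sites for pair ({labels[i]}, {labels[j]})")
    with np.errstate(invalid="ignore"):
        d = np.where(n_comp > 0, (diff & both).sum(axis=-1) / n_comp, 0.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(labels, d, "genetic", "p-distance")


def read_snp_tsv(path) -> pd.DataFrame:
    """Clone x site genotype matrix from TSV (first column = clone label)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_fasta_matrix(path) -> pd.DataFrame:
    """Aligned FASTA to a clone x site character matrix."""
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no sequences in {path}")
    lengths = {len(r.seq) for r in records}
    if len(lengths) != 1:
        raise ValueError("sequences must be aligned (equal length)")
    data = np.array([list(str(r.seq).upper()) for r in records])
    return pd.DataFrame(
        data,
        index=[r.id for r in records],
        columns=[f"s{j + 1:05d}" for j in range(data.shape[1])],
    )


def _lower_triangle(values: np.ndarray) -> np.ndarray:
    i, j = np.tril_indices(values.shape[0], k=-1)
    return values[i, j]


def mantel_test(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int = 9999,
    seed: int = 0,
    tail: str = "greater",
    exhaustive_max_n: int = 7,
) -> MantelResult:
    """Mantel permutation test between two labelled distance matrices.

    The statistic is the Pearson correlation of the lower-triangle
    entries; the null distribution jointly permutes the rows and columns
    of the second matrix.  For n <= ``exhaustive_max_n`` genotypes all
    n! relabelings are enumerated (the identity included), so p is an
    exact multiple of 1/n!.  Otherwise ``n_perm`` random permutations
    plus the identity are used.  ``tail`` is 'greater' (positive
    association, the default), 'less' or 'two-sided'.
    """
    if tuple(d1.labels) != tuple(d2.labels):
        raise ValueError("distance matrices must have matching labels")
    n = len(d1.labels)
    if n < 4:
        raise ValueError("Mantel test needs >= 4 genotypes")
    if tail not in ("greater", "less", "two-sided"):
        raise ValueError("tail must be 'greater', 'less' or 'two-sided'")
    x = _lower_triangle(d1.values)
    if np.ptp(x) == 0 or np.ptp(_lower_triangle(d2.values)) == 0:
        raise ValueError("constant off-diagonal distances: r undefined")

    x = (x - x.mean()) / x.std()
    m = x.size

    def corr_with(perm: np.ndarray) -> float:
        y = _lower_triangle(d2.values[np.ix_(perm, perm)])
        y = (y - y.mean()) / y.std()
        return float((x * y).sum() / m)

    r_obs = corr_with(np.arange(n))

    exhaustive = n <= exhaustive_max_n
    if exhaustive:
        perms = [np.asarray(p) for p in itertools.permutations(range(n))]
    else:
        rng = np.random.default_rng(seed)
        perms = [np.arange(n)] + [rng.permutation(n) for _ in range(n_perm)]
    r_null = np.array([corr_with(p) for p in perms])

    eps = 1e-12
    if tail == "greater":
        p = float(np.mean(r_null >= r_obs - eps))
    elif tail == "less":
        p = float(np.mean(r_null <= r_obs + eps))
    else:
        p = float(np.mean(np.abs(r_null) >= abs(r_obs) - eps))
    return MantelResult(
        r=r_obs,
        p=p,
        n_permutations=len(perms),
        exhaustive=exhaustive,
        tail=tail,
    )
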