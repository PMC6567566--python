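"""Simulation of clonal common-garden experiments with known parameters.

Three generators mirror the three kinds of data the downstream analysis
consumes:

* :func:`simulate_phenotypes` — a genotype x food-level factorial with
  genotype, genotype-by-food and residual effects drawn from zero-mean
  normals (the distributional assumption of the mixed model fitted
  later), so variance-component and heritability estimators can be
  checked by parameter recovery.
* :func:`simulate_growth` — von Bertalanffy body-length trajectories
  with egg and moult events, so life-history trait extraction and curve
  fitting can be checked against the generating parameters.
* :func:`simulate_snp_matrix` — biallelic genotypes produced by placing
  mutations on a clonal genealogy under an infinite-sites rule, so the
  expected pairwise p-distance is exactly (non-shared mutations)/sites.

The default design is five clonal genotypes at two food concentrations
(2.0 and 0.2 mg C per litre) with ten individuals per cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_GENOTYPES = ("A1", "A3", "A5", "A6", "B")
DEFAULT_FOODS = (2.0, 0.2)


@dataclass(frozen=True)
class DesignSpec:
    """Factorial layout of a clonal rearing experiment.

    Parameters
    ----------
    n_genotypes, n_food_levels, n_per_cell
        Numbers of clonal genotypes, food concentrations and replicate
        individuals per genotype x food cell.
    genotype_labels
        Unique genotype identifiers; generated as G01, G02, ... when not
        supplied (the five-clone default uses the panel labels A1..B).
    food_values
        Food concentrations in mg C L^-1, one per level.
    """

    n_genotypes: int = 5
    n_food_levels: int = 2
    n_per_cell: int = 10
    genotype_labels: tuple = ()
    food_values: tuple = ()

    def __post_init__(self):
        if min(self.n_genotypes, self.n_food_levels, self.n_per_cell) < 1:
            raise ValueError("all design counts must be >= 1")
        if not self.genotype_labels:
            if self.n_genotypes == 5:
                labels = DEFAULT_GENOTYPES
            else:
                labels = tuple(f"G{i + 1:02d}" for i in range(self.n_genotypes))
            object.__setattr__(self, "genotype_labels", labels)
        if not self.food_values:
            if self.n_food_levels == 2:
                foods = DEFAULT_FOODS
            else:
                foods = tuple(float(2.0 / (10**i)) for i in range(self.n_food_levels))
            object.__setattr__(self, "food_values", foods)
        if len(self.genotype_labels) != self.n_genotypes:
            raise ValueError("genotype_labels length must equal n_genotypes")
        if len(set(self.genotype_labels)) != self.n_genotypes:
            raise ValueError("genotype labels must be unique")
        if len(self.food_values) != self.n_food_levels:
            raise ValueError("food_values length must equal n_food_levels")


@dataclass(frozen=True)
class TraitModel:
    """Variance-component model for one trait.

    The simulated value of individual k of genotype g at food level f is

        y = grand_mean + food_effect[f] + u_g + w_{gf} + e_k

    with u_g ~ N(0, sigma2_g), w_{gf} ~ N(0, sigma2_gf) and
    e_k ~ N(0, sigma2_e).  Food effects are fixed shifts, one per level.
    """

    trait_name: str
    grand_mean: float
    sigma2_g: float
    sigma2_gf: float = 0.0
    sigma2_e: float = 1.0
    food_effects: tuple = ()

    def __post_init__(self):
        for name in ("sigma2_g", "sigma2_gf", "sigma2_e"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def true_h2(self) -> float:
        """Broad-sense heritability implied by the components."""
        total = self.sigma2_g + self.sigma2_gf + self.sigma2_e
        return self.sigma2_g / total if total > 0 else 0.0


def simulate_phenotypes(
    design: DesignSpec, traits: list[TraitModel], seed: int
) -> pd.DataFrame:
    """Simulate a long-format phenotype table for the given design.

    Genotype and interaction effects are drawn once per genotype (per
    cell for the interaction) and shared by all replicate individuals;
    residuals are per individual.  All randomness flows from ``seed``.

    Returns a DataFrame with columns
    ``individual, genotype, food, trait, value``.
    """
    if not traits:
        raise ValueError("at least one TraitModel is required")
    rng = np.random.default_rng(seed)
    g, f, r = design.n_genotypes, design.n_food_levels, design.n_per_cell
    gen_idx, food_idx, rep_idx = np.meshgrid(
        np.arange(g), np.arange(f), np.arange(r), indexing="ij"
    )
    gen_idx, food_idx, rep_idx = (a.ravel() for a in (gen_idx, food_idx, rep_idx))
    genotype_col = np.asarray(design.genotype_labels)[gen_idx]
    food_col = np.asarray(design.food_values)[food_idx]
    individual = np.array(
        [
            f"{gl}:{fv:g}:{k + 1:02d}"
            for gl, fv, k in zip(genotype_col, food_col, rep_idx)
        ]
    )

    frames = []
    for tm in traits:
        food_effects = np.asarray(tm.food_effects if tm.food_effects else np.zeros(f))
        if food_effects.size != f:
            raise ValueError(
                f"trait {tm.trait_name!r}: food_effects must have one entry per level"
            )
        u = rng.normal(0.0, np.sqrt(tm.sigma2_g), size=g)
        w = rng.normal(0.0, np.sqrt(tm.sigma2_gf), size=(g, f))
        e = rng.normal(0.0, np.sqrt(tm.sigma2_e), size=g * f * r)
        value = (
            tm.grand_mean
            + food_effects[food_idx]
            + u[gen_idx]
            + w[gen_idx, food_idx]
            + e
        )
        frames.append(
            pd.DataFrame(
                {
                    "individual": individual,
                    "genotype": genotype_col,
                    "food": food_col,
                    "trait": tm.trait_name,
                    "value": value,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def von_bertalanffy_length(t, l_inf: float, k: float, t0: float):
    """Expected body length L_t = L_inf * (1 - exp(-k (t - t0)))."""
    return l_inf * (1.0 - np.exp(-k * (np.asarray(t, dtype=float) - t0)))


def simulate_growth(
    design: DesignSpec,
    l_inf: float = 2.45,
    k: float = 0.11,
    t0: float = 0.0,
    noise_sd: float = 0.02,
    seed: int = 0,
    *,
    t_max: int = 30,
    l_inf_genotype_sd: float = 0.0,
    k_genotype_sd: float = 0.0,
    maturation_age_mean: float = 7.6,
    maturation_age_sd: float = 1.0,
    clutch_mean: float = 6.2,
    intermoult_pre: float = 1.9,
    intermoult_post: float = 2.3,
    tail_spine_ratio: float = 0.19,
    neonate_size_mean: float = 0.63,
    neonate_size_sd: float = 0.05,
) -> pd.DataFrame:
    """Simulate daily growth trajectories for every design individual.

    Body length at integer ages 1..t_max follows the von Bertalanffy
    curve with Gaussian measurement noise.  Optional multiplicative
    lognormal genotype effects on L_inf and k introduce heritable
    growth variation.  Each individual matures at a latent age drawn
    from N(maturation_age_mean, maturation_age_sd); after that age a
    Poisson(clutch_mean) clutch is carried per adult instar, and the
    first age with a positive egg count is the observable maturation
    age.  Moult counts per day and tail-spine lengths are included so
    the full life-history trait set is derivable.

    The trajectory horizon of 30 days is long enough for roughly six
    clutches at the default intermoult durations.
    """
    if l_inf <= 0 or k <= 0:
        raise ValueError("l_inf and k must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    ages = np.arange(1, t_max + 1, dtype=float)

    g_linf = np.exp(rng.normal(0.0, l_inf_genotype_sd, size=design.n_genotypes))
    g_k = np.exp(rng.normal(0.0, k_genotype_sd, size=design.n_genotypes))

    rows = []
    for gi, gl in enumerate(design.genotype_labels):
        for fv in design.food_values:
            for rep in range(design.n_per_cell):
                ind = f"{gl}:{fv:g}:{rep + 1:02d}"
                li, ki = l_inf * g_linf[gi], k * g_k[gi]
                length = von_bertalanffy_length(ages, li, ki, t0)
                length = length + rng.normal(0.0, noise_sd, size=ages.size)
                mat_age = max(2.0, rng.normal(maturation_age_mean, maturation_age_sd))
                # moult schedule: juvenile cadence before maturation, adult after
                moult_times = []
                t = intermoult_pre
                while t < mat_age:
                    moult_times.append(t)
                    t += intermoult_pre
                while t <= t_max:
                    moult_times.append(t)
                    t += intermoult_post
                moult_times = np.asarray(moult_times)
                moults_per_day = np.array(
                    [
                        int(np.sum((moult_times > a - 1) & (moult_times <= a)))
                        for a in ages
                    ]
                )
                # one latent clutch per adult instar; eggs observable once positive
                adult_instar_starts = np.concatenate(
                    [[mat_age], moult_times[moult_times >= mat_age]]
                )
                eggs = np.zeros(ages.size, dtype=int)
                for start, stop in zip(
                    adult_instar_starts,
                    np.append(adult_instar_starts[1:], t_max + 1),
                ):
                    clutch = rng.poisson(clutch_mean)
                    eggs[(ages >= start) & (ages < stop)] = clutch
                tail = tail_spine_ratio * length + rng.normal(
                    0.0, noise_sd / 2 if noise_sd > 0 else 0.0, size=ages.size
                )
                neonate = np.where(
                    eggs > 0,
                    rng.normal(neonate_size_mean, neonate_size_sd, size=ages.size),
                    np.nan,
                )
                rows.append(
                    pd.DataFrame(
                        {
                            "individual": ind,
                            "genotype": gl,
                            "food": fv,
                            "age_d": ages,
                            "body_length_mm": length,
                            "tail_spine_mm": tail,
                            "egg_count": eggs,
                            "moult": moults_per_day,
                            "neonate_size_mm": neonate,
                        }
                    )
                )
    return pd.concat(rows, ignore_index=True)


@dataclass(frozen=True)
class CloneGenealogySpec:
    """A clonal genealogy with per-branch mutation counts.

    ``edges`` lists (parent, child) node pairs; tip nodes are the clone
    labels.  ``branch_mutation_counts`` gives the number of substituted
    sites on each edge, aligned with ``edges``.  Mutations follow an
    infinite-sites rule — every mutation in the genealogy hits its own
    site — so the pairwise p-distance between two clones is exactly the
    summed mutation count on the path between them divided by
    ``n_sites``.
    """

    n_sites: int
    topology: str
    clone_labels: tuple
    edges: tuple  # of (parent, child)
    branch_mutation_counts: tuple

    def __post_init__(self):
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if len(self.edges) != len(self.branch_mutation_counts):
            raise ValueError("one mutation count per edge required")
        if any(c < 0 for c in self.branch_mutation_counts):
            raise ValueError("mutation counts must be non-negative")
        if max(self.branch_mutation_counts, default=0) > self.n_sites:
            raise ValueError("branch mutation count exceeds n_sites")
        if sum(self.branch_mutation_counts) > self.n_sites:
            raise ValueError("total mutations exceed n_sites (infinite-sites rule)")

    @classmethod
    def star(cls, labels, mutation_counts, n_sites: int) -> "CloneGenealogySpec":
        """Star genealogy: every clone on its own branch from the root."""
        labels = tuple(labels)
        edges = tuple(("root", lab) for lab in labels)
        return cls(n_sites, "star", labels, edges, tuple(mutation_counts))

    @classmethod
    def caterpillar(
        cls, labels, tip_counts, internal_counts, n_sites: int
    ) -> "CloneGenealogySpec":
        """Ladder-shaped bifurcating genealogy ((((c1,c2),c3),...),cn).

        ``internal_counts`` has one entry per internal edge, i.e.
        ``len(labels) - 2`` entries for >= 3 clones.
        """
        labels = tuple(labels)
        n = len(labels)
        if n < 2:
            raise ValueError("need >= 2 clones")
        if len(internal_counts) != max(0, n - 2):
            raise ValueError(f"expected {max(0, n - 2)} internal edge counts")
        edges, counts = [], []
        # internal spine: root -> I_{n-1} -> ... -> I_2; clade I_j = {c1..cj}
        parents = ["root"] + [f"I{j}" for j in range(n - 1, 1, -1)]
        for parent, child, c in zip(
            parents[:-1], parents[1:], reversed(tuple(internal_counts))
        ):
            edges.append((parent, child))
            counts.append(c)
        # tips: c1, c2 hang off I2 (or root when n == 2); c_j off I_j's parent spine
        tip_parent = {labels[0]: parents[-1], labels[1]: parents[-1]}
        for j in range(3, n + 1):
            tip_parent[labels[j - 1]] = parents[n - j]
        for lab, c in zip(labels, tip_counts):
            edges.append((tip_parent[lab], lab))
            counts.append(c)
        return cls(n_sites, "bifurcating", labels, tuple(edges), tuple(counts))


def simulate_snp_matrix(spec: CloneGenealogySpec, seed: int) -> pd.DataFrame:
    """Drop mutations on the genealogy and read off tip genotypes.

    Distinct sites are assigned to every mutation in the genealogy
    (without replacement across all branches); each clone carries the
    union of mutations on its root-to-tip path.  Returns a clone x site
    0/1 DataFrame whose pairwise p-distances equal path lengths divided
    by ``n_sites`` by construction.
    """
    rng = np.random.default_rng(seed)
    total = int(sum(spec.branch_mutation_counts))
    sites = rng.choice(spec.n_sites, size=total, replace=False)
    edge_sites: dict = {}
    pos = 0
    for edge, count in zip(spec.edges, spec.branch_mutation_counts):
        edge_sites[edge] = sites[pos : pos + count]
        pos += count
    parent_of = {child: parent for parent, child in spec.edges}

    matrix = np.zeros((len(spec.clone_labels), spec.n_sites), dtype=np.int8)
    for i, clone in enumerate(spec.clone_labels):
        node = clone
        while node in parent_of:
            parent = parent_of[node]
            matrix[i, edge_sites[(parent, node)]] = 1
            node = parent
    columns = [f"s{j + 1:05d}" for j in range(spec.n_sites)]
    return pd.DataFrame(matrix, index=list(spec.clone_labels), columns=columns)
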