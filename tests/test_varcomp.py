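"""Variance decomposition: ANOVA arithmetic, EMS moments and REML."""

import numpy as np
import pandas as pd
import pytest

from clonalquant import (
    DesignSpec,
    TraitModel,
    anova_two_way,
    ems_decompose,
    reml_decompose,
    simulate_phenotypes,
    variance_percent,
)


def brute_force_anova(table):
    """Independent sums-of-squares oracle: explicit mean arithmetic."""
    df = table
    grand = df["value"].mean()
    g_means = df.groupby("genotype")["value"].mean()
    f_means = df.groupby("food")["value"].mean()
    cell_means = df.groupby(["genotype", "food"])["value"].mean()
    g, f = len(g_means), len(f_means)
    r = len(df) // (g * f)
    ss_g = f * r * sum((m - grand) ** 2 for m in g_means)
    ss_f = g * r * sum((m - grand) ** 2 for m in f_means)
    ss_gf = r * sum(
        (cell_means[(gi, fi)] - g_means[gi] - f_means[fi] + grand) ** 2
        for gi in g_means.index
        for fi in f_means.index
    )
    ss_e = sum(
        (row.value - cell_means[(row.genotype, row.food)]) ** 2
        for row in df.itertuples()
    )
    return ss_g, ss_f, ss_gf, ss_e


class TestAnova:
    def test_toy_table_matches_hand_arithmetic(self, toy_2x2x2):
        out = anova_two_way(toy_2x2x2, "t")
        ss_g, ss_f, ss_gf, ss_e = brute_force_anova(toy_2x2x2)
        assert out.loc["genotype", "ss"] == pytest.approx(ss_g)
        assert out.loc["food", "ss"] == pytest.approx(ss_f)
        assert out.loc["interaction", "ss"] == pytest.approx(ss_gf)
        assert out.loc["residual", "ss"] == pytest.approx(ss_e)
        # mixed-model error terms
        assert out.loc["genotype", "F"] == pytest.approx(
            out.loc["genotype", "ms"] / out.loc["interaction", "ms"]
        )
        assert out.loc["interaction", "F"] == pytest.approx(
            out.loc["interaction", "ms"] / out.loc["residual", "ms"]
        )

    def test_food_shift_only_design(self, make_table):
        tab = make_table(g=5, f=2, r=10, s2g=0.0, s2gf=0.0, s2e=0.01,
                         food_effects=(0.0, -5.0), seed=3)
        out = anova_two_way(tab, "t")
        assert out.loc["food", "F"] > 1000
        assert out.loc["genotype", "F"] < 10
        assert out.loc["food", "p"] < 1e-6

    def test_requires_replication(self, make_table):
        tab = make_table(g=3, f=2, r=1)
        with pytest.raises(ValueError):
            anova_two_way(tab, "t")


class TestEmsDecompose:
    def test_constant_data_gives_zero_components(self, make_table):
        tab = make_table(s2g=0.0, s2gf=0.0, s2e=0.0)
        d = ems_decompose(tab, "t")
        assert (d.sigma2_g, d.sigma2_gf, d.sigma2_e) == (0.0, 0.0, 0.0)

    def test_parameter_recovery_large_design(self, make_table):
        # mean over seeds: sigma2_g has sampling sd ~ 4*sqrt(2/49) = 0.8 per
        # dataset at 50 genotypes, so the estimator is judged on its average
        decomps = [
            ems_decompose(
                make_table(g=50, f=2, r=20, s2g=4.0, s2gf=1.0, s2e=1.0, seed=s),
                "t",
            )
            for s in range(30)
        ]
        assert np.mean([d.sigma2_g for d in decomps]) == pytest.approx(4.0, rel=0.15)
        assert np.mean([d.sigma2_gf for d in decomps]) == pytest.approx(1.0, rel=0.15)
        assert np.mean([d.sigma2_e for d in decomps]) == pytest.approx(1.0, rel=0.15)

    def test_negative_genotype_component_truncated(self):
        # genotype means nearly equal but strong interaction: MS_G < MS_GxF
        rows = []
        cell = {("g1", 0): 0.0, ("g1", 1): 10.0, ("g2", 0): 10.0, ("g2", 1): 0.0}
        rng = np.random.default_rng(0)
        for (g, f), m in cell.items():
            for i in range(5):
                rows.append(
                    dict(individual=f"{g}{f}{i}", genotype=g, food=f,
                         trait="t", value=m + rng.normal(0, 0.1))
                )
        d = ems_decompose(pd.DataFrame(rows), "t")
        assert d.sigma2_g == 0.0
        assert d.sigma2_gf > 0

    def test_unbalanced_rejected_pointing_to_reml(self, make_table):
        tab = make_table().drop(index=[0, 1, 2]).reset_index(drop=True)
        with pytest.raises(ValueError, match="reml"):
            ems_decompose(tab, "t")

    def test_shift_and_scale_equivariance(self, make_table):
        tab = make_table(seed=11)
        base = ems_decompose(tab, "t")
        shifted = tab.copy()
        shifted["value"] += 100.0
        d_shift = ems_decompose(shifted, "t")
        assert d_shift.sigma2_g == pytest.approx(base.sigma2_g, rel=1e-9)
        scaled = tab.copy()
        scaled["value"] *= 3.0
        d_scale = ems_decompose(scaled, "t")
        assert d_scale.sigma2_g == pytest.approx(9.0 * base.sigma2_g, rel=1e-9)
        assert d_scale.sigma2_e == pytest.approx(9.0 * base.sigma2_e, rel=1e-9)


class TestRemlDecompose:
    def test_matches_ems_on_balanced_interior_data(self, make_table):
        tab = make_table(g=10, f=2, r=8, s2g=3.0, s2gf=1.0, s2e=1.0, seed=5)
        ems = ems_decompose(tab, "t")
        reml = reml_decompose(tab, "t")
        assert ems.sigma2_g > 0 and ems.sigma2_gf > 0  # interior
        for attr in ("sigma2_g", "sigma2_gf", "sigma2_e"):
            assert getattr(reml, attr) == pytest.approx(
                getattr(ems, attr), rel=1e-6
            )

    def test_zero_genotype_variance_estimated_at_boundary(self):
        design = DesignSpec(5, 2, 5)
        at_zero = 0
        n_rep = 60
        for i in range(n_rep):
            tab = simulate_phenotypes(
                design, [TraitModel("t", 0.0, 0.0, 0.0, 1.0)], seed=500 + i
            )
            d = reml_decompose(tab, "t")
            at_zero += d.sigma2_g < 1e-8
        assert at_zero > n_rep / 2

    def test_matches_statsmodels_on_unbalanced_data(self, make_table):
        import statsmodels.formula.api as smf

        tab = make_table(g=6, f=2, r=8, s2g=4.0, s2gf=1.0, s2e=1.0, seed=11)
        rng = np.random.default_rng(5)
        tab = tab.drop(index=rng.choice(tab.index, 15, replace=False))
        mine = reml_decompose(tab, "t")

        sub = tab.copy()
        sub["food"] = sub["food"].astype(str)
        fit = smf.mixedlm(
            "value ~ C(food)", sub, groups=sub["genotype"],
            re_formula="1", vc_formula={"gxf": "0 + C(food)"},
        ).fit(reml=True, method="lbfgs")
        assert mine.sigma2_g == pytest.approx(float(fit.cov_re.iloc[0, 0]), rel=1e-3)
        assert mine.sigma2_gf == pytest.approx(float(fit.vcomp[0]), rel=1e-3)
        assert mine.sigma2_e == pytest.approx(float(fit.scale), rel=1e-3)


class TestVariancePercent:
    def test_simple_shares(self, make_table):
        tab = make_table()
        d = ems_decompose(tab, "t")
        d.sigma2_g, d.sigma2_gf, d.sigma2_e = 1.0, 1.0, 2.0
        pct = variance_percent(d)
        assert pct == {"genotype": 25.0, "interaction": 25.0, "residual": 50.0}

    def test_zero_genotype_component_gives_zero_percent(self, make_table):
        d = ems_decompose(make_table(), "t")
        d.sigma2_g = 0.0
        assert variance_percent(d)["genotype"] == 0.0

    def test_percents_close_to_hundred(self, make_table):
        d = ems_decompose(make_table(seed=2), "t")
        assert sum(variance_percent(d).values()) == pytest.approx(100.0)
        assert sum(variance_percent(d, include_fixed=True).values()) == (
            pytest.approx(100.0)
        )

    def test_all_zero_total_by_convention(self, make_table):
        d = ems_decompose(make_table(s2g=0.0, s2gf=0.0, s2e=0.0), "t")
        assert set(variance_percent(d).values()) == {0.0}
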