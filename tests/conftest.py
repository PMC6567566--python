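import numpy as np
import pandas as pd
import pytest

from clonalquant import DesignSpec, TraitModel, simulate_phenotypes


@pytest.fixture
def make_table():
    """Factory for simulated balanced phenotype tables."""

    def _make(
        g=5, f=2, r=10, s2g=2.0, s2gf=0.5, s2e=1.0, mean=10.0,
        food_effects=None, seed=0, trait="t",
    ):
        design = DesignSpec(g, f, r)
        tm = TraitModel(
            trait, mean, s2g, s2gf, s2e,
            food_effects=tuple(food_effects) if food_effects else (),
        )
        return simulate_phenotypes(design, [tm], seed=seed)

    return _make


@pytest.fixture
def toy_2x2x2():
    """Tiny balanced table whose ANOVA can be checked by hand."""
    rows = []
    values = {
        ("g1", 0.0): (1.0, 2.0),
        ("g1", 1.0): (4.0, 6.0),
        ("g2", 0.0): (3.0, 5.0),
        ("g2", 1.0): (7.0, 12.0),
    }
    for (g, f), (a, b) in values.items():
        for i, v in enumerate((a, b)):
            rows.append(
                {
                    "individual": f"{g}:{f}:{i}",
                    "genotype": g,
                    "food": f,
                    "trait": "t",
                    "value": v,
                }
            )
    return pd.DataFrame(rows)
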