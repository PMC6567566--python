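"""Published summary statistics for the five-clone *D. pulex* JPN1 panel.

The panel comprises five obligately parthenogenetic genotypes (A1, A3,
A5, A6, B) assayed at food levels of 2.0 and 0.2 mg C L^-1 for 17
traits in three categories.  These per-trait summaries — trait means,
among-genotype (genetic) variances, broad-sense heritabilities with
bootstrap confidence intervals, and genetic CVs — together with the
BLUP-PCA eigenvalue spectrum serve as worked-example inputs: the raw
individual-level data are not redistributed here, but the derived
quantities (CV from Vg and the mean, heritability summaries, PCA
contribution rates) can be recomputed from these numbers and checked
against the printed values.

Note two known quirks of the published table, preserved as printed:
the lipase CV (38.42%) is not consistent with 100*sqrt(Vg)/mean from
the printed Vg and mean, and some bootstrap CIs exclude their point
estimate.  Small printed Vg values are rounded aggressively, so CVs
recompute exactly only for traits whose Vg carries enough digits.
"""

from __future__ import annotations

import pandas as pd

GENOTYPES = ("A1", "A3", "A5", "A6", "B")
FOOD_LEVELS_MG_C_PER_L = (2.0, 0.2)

# columns: category, mean, vg, h2, ci_low, ci_high, cv_percent
_TRAITS = {
    "beta_glucosidase":          ("digestive",    322.89, 1630.00, 0.35, 0.00, 0.31, 12.51),
    "lipase":                    ("digestive",   1949.41, 8489.41, 0.07, 0.00, 0.17, 38.42),
    "alkaline_phosphatase":      ("digestive",    764.47, 13060.00, 0.36, 0.00, 0.63, 14.95),
    "arginine_aminopeptidase":   ("digestive",    195.93, 2128.45, 0.41, 0.28, 0.80, 23.55),
    "alanine_aminopeptidase":    ("digestive",    178.05, 845.20, 0.56, 0.48, 0.91, 16.33),
    "maturation_age":            ("life_history",   7.62, 0.48, 0.41, 0.10, 0.73, 9.08),
    "maturation_instar":         ("life_history",   3.14, 0.13, 0.20, 0.01, 0.61, 11.64),
    "maturation_body_length":    ("life_history",   1.61, 0.004, 0.28, 0.00, 0.08, 3.92),
    "intermoult_pre_maturation": ("life_history",   1.94, 0.001, 0.09, 0.00, 0.48, 1.95),
    "intermoult_post_maturation": ("life_history",  2.31, 0.00, 0.00, 0.00, 0.19, 0.00),
    "k":                         ("life_history",   0.11, 0.0002, 0.12, 0.04, 0.71, 12.86),
    "mean_egg_number":           ("life_history",   6.19, 0.28, 0.23, 0.00, 0.57, 8.54),
    "mean_neonate_size":         ("morphology",     0.63, 0.00006, 0.04, 0.00, 0.08, 1.22),
    "body_length_day5":          ("morphology",     1.29, 0.02, 0.67, 0.66, 0.85, 9.83),
    "body_weight_day5":          ("morphology",     0.02, 0.00002, 0.58, 0.66, 0.87, 27.61),
    "relative_tail_spine":       ("morphology",     0.19, 0.001, 0.91, 0.44, 0.72, 17.99),
    "l_inf":                     ("morphology",     2.45, 0.01, 0.31, 0.00, 0.57, 4.41),
}


def trait_summaries() -> pd.DataFrame:
    """Per-trait published summary statistics for the JPN1 panel."""
    frame = pd.DataFrame.from_dict(
        _TRAITS,
        orient="index",
        columns=["category", "mean", "vg", "h2", "ci_low", "ci_high", "cv_percent"],
    )
    frame.index.name = "trait"
    return frame


#: Traits whose printed Vg carries enough digits for the CV identity
#: 100 * sqrt(Vg) / mean to recompute at printed precision.
CV_WORKED_EXAMPLES = (
    "alkaline_phosphatase",
    "arginine_aminopeptidase",
    "alanine_aminopeptidase",
    "k",
)

#: Eigenvalue spectrum of the BLUP-trait PCA (14 heritable traits,
#: components retained by the eigenvalue > 1 rule) and the printed
#: per-component variance-contribution rates.
PCA_N_TRAITS = 14
PCA_EIGENVALUES = (7.33, 4.62, 1.12)
PCA_CONTRIBUTION_PERCENT = (52.35, 33.03, 8.03)
PCA_CUMULATIVE_PERCENT = (52.35, 85.38, 93.41)
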