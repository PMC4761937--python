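"""End-to-end convenience wrappers tying the analysis stages together.

These functions run the standard study analysis on a generated (or
loaded) expression study: DE selection for both assays with the set
algebra, and the coverage-stratified steady-state-protein regression
grid.  They are thin glue over the per-stage modules.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import diffexpr, integrate, proteomics, quantify
from .synthetic import ExpressionStudy


def rp_de_selection(study: ExpressionStudy, frac: float = 0.10) -> diffexpr.DESelection:
    """NB exact test + top-fraction FDR selection on the RP count tables."""
    m, g1 = study.tables[("RP", "M")], study.tables[("RP", "G1")]
    joint = pd.concat([m, g1], axis=1)
    conditions = np.array(["M"] * m.shape[1] + ["G1"] * g1.shape[1])
    fit = diffexpr.fit_nb(joint, conditions)
    pvals = diffexpr.nb_test(m, g1, fit)
    lfc = diffexpr.log2_fold_change(m, g1, fit)
    return diffexpr.select_top_fraction(pvals, lfc, frac=frac)


def pp_de_selection(
    study: ExpressionStudy, frac: float = 0.10, fdr: float = 0.01
) -> tuple[diffexpr.DESelection, pd.Index]:
    """PUNCH-P filtering cascade + ANOVA fold-change selection.

    Returns the selection and the tested universe (proteins quantified
    in both phases after filtering).
    """
    phase_cols = {ph: list(study.tables[("PP", ph)].columns) for ph in ("M", "G1")}
    raw = pd.concat(
        [study.tables[("PP", "M")], study.tables[("PP", "G1")], study.pp_control], axis=1
    )
    filtered = proteomics.filter_punch_p(
        raw, list(study.pp_control.columns), phase_cols, fdr=fdr
    )
    universe = filtered.dropna().index
    m = proteomics.impute_lowest(study.tables[("PP", "M")]).loc[universe]
    g1 = proteomics.impute_lowest(study.tables[("PP", "G1")]).loc[universe]
    return diffexpr.anova_fc_select(m, g1, frac=frac), universe


def analysis_vectors(study: ExpressionStudy, phase: str) -> dict[str, pd.Series]:
    """Replicate-averaged, log2-scale per-gene vectors for one phase."""
    return {
        "mRNA": integrate.log2_with_pseudo(
            quantify.average_replicates(study.tables[("mRNA", phase)])
        ),
        "RP": integrate.log2_with_pseudo(
            quantify.average_replicates(study.tables[("RP", phase)])
        ),
        "PP": study.tables[("PP", phase)].mean(axis=1),
        "PSS": study.tables[("PSS", phase)].mean(axis=1),
    }


def regression_grid(
    study: ExpressionStudy, phase: str, seed: int = 0, repeats: int = 100
) -> list[integrate.RegressionReport]:
    """PP / PP+RP / PP+RP+mRNA regression of PSS across coverage groups."""
    vec = analysis_vectors(study, phase)
    predictors = {k: vec[k] for k in ("mRNA", "RP", "PP")}
    return integrate.regression_grid(
        predictors, vec["PSS"], study.coverage, seed=seed, repeats=repeats
    )
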