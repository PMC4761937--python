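"""Label-free MS intensity filtering for nascent-chain (PUNCH-P) and
steady-state protein data.

The PUNCH-P design has 3 non-specific (non-puromycylated) control
replicates and 12 experimental samples (4 time points x 3 replicates).
Filtering proceeds in a fixed order: lowest-value imputation of missing
intensities (18 on the log2 scale), a per-protein specificity t-test of
experimental vs control at 1% FDR, a detected-in->=2-of-3-replicates
filter per phase evaluated on the *pre-imputation* detection mask, then
per-phase triplicate averaging.

Missing values are explicit (NaN), never encoded as zero.  Intensities
are assumed log2-scale throughout; Welch's t-test (two-sided) is used
for the unequal group sizes, with Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

IMPUTE_VALUE = 18.0  # lowest observed log2 intensity in the source data


def impute_lowest(matrix: pd.DataFrame, value: float = IMPUTE_VALUE) -> pd.DataFrame:
    """Replace every missing intensity with the lowest-intensity constant."""
    return matrix.fillna(value)


def specificity_filter(
    matrix: pd.DataFrame,
    control_cols: list[str],
    experimental_cols: list[str],
    fdr: float = 0.01,
) -> pd.Index:
    """Proteins whose experimental signal differs from the control background.

    Per-protein Welch t-test of the experimental samples against the
    controls (imputation should already have been applied), BH-adjusted;
    proteins with q <= ``fdr`` are retained.  Rows with zero variance in
    both groups get p = 1 by convention.
    """
    exp = matrix[experimental_cols].to_numpy(dtype=float)
    ctl = matrix[control_cols].to_numpy(dtype=float)
    if exp.shape[1] < 2 or ctl.shape[1] < 2:
        raise ValueError("need >=2 samples per group for a t-test")
    with warnings.catch_warnings():
        # zero-variance rows are assigned p = 1 below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(exp, ctl, axis=1, equal_var=False)
    pvals = np.asarray(res.pvalue, dtype=float)
    degenerate = (exp.std(axis=1) == 0) & (ctl.std(axis=1) == 0)
    pvals[degenerate | ~np.isfinite(pvals)] = 1.0
    reject, _, _, _ = multipletests(pvals, alpha=fdr, method="fdr_bh")
    return matrix.index[reject]


def min_replicate_filter(
    matrix: pd.DataFrame, phase_cols: dict[str, list[str]], k: int = 2
) -> dict[str, pd.Index]:
    """Per phase, proteins detected (non-missing) in >= ``k`` replicates.

    Detection is evaluated on the raw matrix, before imputation.
    """
    out = {}
    for phase, cols in phase_cols.items():
        detected = matrix[cols].notna().sum(axis=1)
        out[phase] = matrix.index[detected >= k]
    return out


def average_triplicates(
    matrix: pd.DataFrame, phase_cols: dict[str, list[str]]
) -> pd.DataFrame:
    """Arithmetic mean of the replicate intensities per phase."""
    return pd.DataFrame({phase: matrix[cols].mean(axis=1) for phase, cols in phase_cols.items()})


def filter_punch_p(
    raw: pd.DataFrame,
    control_cols: list[str],
    phase_cols: dict[str, list[str]],
    fdr: float = 0.01,
    impute_value: float = IMPUTE_VALUE,
    min_detected: int = 2,
) -> pd.DataFrame:
    """Full PUNCH-P filtering cascade; returns per-phase averaged intensities.

    Order: impute -> specificity t-test (pooled experimental vs control)
    -> min-replicate filter on the pre-imputation detection mask ->
    triplicate averaging.  Proteins failing a phase's detection filter
    get NaN for that phase.
    """
    experimental_cols = [c for cols in phase_cols.values() for c in cols]
    imputed = impute_lowest(raw, impute_value)
    specific = specificity_filter(imputed, control_cols, experimental_cols, fdr=fdr)
    kept = imputed.loc[specific]
    detected = min_replicate_filter(raw.loc[specific], phase_cols, k=min_detected)
    averaged = average_triplicates(kept, phase_cols)
    for phase in phase_cols:
        averaged.loc[~averaged.index.isin(detected[phase]), phase] = np.nan
    return averaged


def filter_steady_state(
    raw: pd.DataFrame, phase_cols: dict[str, list[str]], min_detected: int = 2
) -> pd.DataFrame:
    """Steady-state protein filtering: detection filter + triplicate average.

    No specificity test (there is no control arm); missing values among
    detected proteins are ignored in the mean.
    """
    detected = min_replicate_filter(raw, phase_cols, k=min_detected)
    averaged = average_triplicates(raw, phase_cols)
    for phase in phase_cols:
        averaged.loc[~averaged.index.isin(detected[phase]), phase] = np.nan
    return averaged
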