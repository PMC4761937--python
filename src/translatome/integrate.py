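"""Correlation and regression analyses linking mRNA, ribosome occupancy,
nascent-chain proteomics and steady-state protein levels.

All headline correlations are Spearman.  Steady-state protein prediction
uses ordinary least squares on log2-scale predictors, scored by the
Spearman correlation of held-out predictions over 100 repeats of 2-fold
cross-validation, stratified by ribosome-footprint coverage group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

COVERAGE_THRESHOLDS = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6)


def _clean_pair(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    return x[ok], y[ok]


def spearman(x, y) -> float:
    """Spearman rank correlation; pairs with missing values are dropped."""
    x, y = _clean_pair(x, y)
    if len(x) < 3:
        raise ValueError("need >=3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(stats.spearmanr(x, y).statistic)


def partial_spearman(x, y, z) -> float:
    """Rank-based partial correlation of x and y controlling for z.

    Variables are rank-transformed (ties averaged), z is removed from
    each by least squares, and the residuals are correlated.  A constant
    z reduces to the plain Spearman correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y) & np.isfinite(z)
    x, y, z = x[ok], y[ok], z[ok]
    if len(x) < 4:
        raise ValueError("need >=4 complete triples")
    rx, ry, rz = (stats.rankdata(v) for v in (x, y, z))
    if np.ptp(rz) == 0:
        return spearman(x, y)
    design = np.column_stack([np.ones_like(rz), rz])
    res_x = rx - design @ np.linalg.lstsq(design, rx, rcond=None)[0]
    res_y = ry - design @ np.linalg.lstsq(design, ry, rcond=None)[0]
    if np.allclose(res_x, 0) or np.allclose(res_y, 0):
        raise ValueError("no residual variance after removing the control variable")
    return float(np.corrcoef(res_x, res_y)[0, 1])


def binned_correlation(x, y, bin_by, n_bins: int, min_per_bin: int = 10):
    """Per-bin Spearman of x and y for equal-size bins sorted by ``bin_by``.

    Returns a DataFrame with bin index, n, the bin's ``bin_by`` range
    and rho.  If the data cannot fill ``n_bins`` bins of at least
    ``min_per_bin``, fewer bins are used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    b = np.asarray(bin_by, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y) & np.isfinite(b)
    x, y, b = x[ok], y[ok], b[ok]
    n_bins = max(1, min(n_bins, len(x) // min_per_bin))
    order = np.argsort(b, kind="mergesort")
    rows = []
    for i, idx in enumerate(np.array_split(order, n_bins)):
        rows.append(
            {
                "bin": i,
                "n": len(idx),
                "lo": float(b[idx].min()),
                "hi": float(b[idx].max()),
                "rho": spearman(x[idx], y[idx]),
            }
        )
    return pd.DataFrame(rows)


def coverage_groups(coverage: pd.Series) -> dict[str, pd.Series]:
    """The seven nested footprint-coverage gene masks (>0 up to >=60%)."""
    cov = coverage.astype(float)
    if ((cov < 0) | (cov > 1)).any():
        raise ValueError("coverage must lie in [0, 1]")
    masks = {">0": cov > 0}
    for thr in COVERAGE_THRESHOLDS[1:]:
        masks[f">={int(thr * 100)}%"] = cov >= thr
    return masks


@dataclass
class RegressionReport:
    predictors: str
    coverage_group: str
    mean_rho: float
    sd_rho: float
    n_genes: int
    folds: int = 2
    repeats: int = 100


def cv_regression(
    predictors: pd.DataFrame,
    response: pd.Series,
    folds: int = 2,
    repeats: int = 100,
    seed: int = 0,
    label: str = "",
    coverage_group: str = "",
) -> RegressionReport:
    """Repeated k-fold OLS scored by held-out Spearman correlation.

    Per repeat the genes are split at random into ``folds`` folds; an
    ordinary least-squares fit on the training folds predicts the
    held-out fold, and the prediction is scored against the observed
    response by Spearman correlation.  Reports mean and SD over all
    ``folds * repeats`` fold scores.
    """
    data = predictors.join(response.rename("__y__"), how="inner").dropna()
    n, p = len(data), predictors.shape[1]
    if n < folds * (p + 2):
        raise ValueError(f"too few genes ({n}) for {folds}-fold regression with {p} predictors")
    X = np.column_stack([np.ones(n), data.drop(columns="__y__").to_numpy(dtype=float)])
    y = data["__y__"].to_numpy(dtype=float)

    rng = np.random.default_rng(seed)
    scores = []
    for _ in range(repeats):
        perm = rng.permutation(n)
        for f in range(folds):
            test = perm[f::folds]
            train = np.setdiff1d(perm, test)
            beta = np.linalg.lstsq(X[train], y[train], rcond=None)[0]
            scores.append(spearman(X[test] @ beta, y[test]))
    scores = np.asarray(scores)
    return RegressionReport(
        predictors=label or "+".join(predictors.columns),
        coverage_group=coverage_group,
        mean_rho=float(scores.mean()),
        sd_rho=float(scores.std(ddof=1)),
        n_genes=n,
        folds=folds,
        repeats=repeats,
    )


def regression_grid(
    tables: dict[str, pd.Series],
    response: pd.Series,
    coverage: pd.Series,
    predictor_sets: dict[str, list[str]] | None = None,
    folds: int = 2,
    repeats: int = 100,
    seed: int = 0,
) -> list[RegressionReport]:
    """The coverage-stratified regression grid for the standard
    predictor ladder PP, PP+RP, PP+RP+mRNA."""
    if predictor_sets is None:
        predictor_sets = {
            "PP": ["PP"],
            "PP+RP": ["PP", "RP"],
            "PP+RP+mRNA": ["PP", "RP", "mRNA"],
        }
    frame = pd.DataFrame(tables)
    reports = []
    for group, mask in coverage_groups(coverage).items():
        genes = mask.index[mask]
        for label, cols in predictor_sets.items():
            reports.append(
                cv_regression(
                    frame.loc[frame.index.intersection(genes), cols],
                    response,
                    folds=folds,
                    repeats=repeats,
                    seed=seed,
                    label=label,
                    coverage_group=group,
                )
            )
    return reports


def log2_with_pseudo(x: pd.Series) -> pd.Series:
    """log2(x + eps) with eps = half the smallest positive value."""
    arr = x.astype(float)
    pos = arr[arr > 0]
    if pos.empty:
        raise ValueError("no positive values to set a pseudo-count from")
    return np.log2(arr + pos.min() / 2)
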