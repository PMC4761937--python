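"""M-vs-G1 differential expression and the RP/PP set algebra.

Ribosome-profiling counts are tested with the classic negative-binomial
exact test: samples are normalized by median-of-ratios size factors, a
mean-variance relationship is fitted across genes by local regression,
and each gene's M-total vs G1-total is tested conditionally on the grand
total under the fitted NB model.  Nascent-chain (PUNCH-P) intensities
are tested per gene with one-way ANOVA and ranked by significant
fold-change.  Both assays select the top 10% of the tested universe as
differentially expressed; the resulting sets are compared by exact set
algebra and an upper-tail hypergeometric overlap test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

__all__ = [
    "size_factors",
    "NBFit",
    "fit_nb",
    "nb_test",
    "select_top_fraction",
    "anova_fc_select",
    "GeneSets",
    "set_algebra",
    "hypergeom_overlap",
    "opposite_direction_groups",
]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization factors, scaled to geometric mean 1.

    ``s_j = median_i  k_ij / (prod_j k_ij)^(1/m)`` over genes with
    nonzero counts in every sample.
    """
    k = counts.to_numpy(dtype=float)
    positive = (k > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no gene has nonzero counts in all samples; size factors need a pseudo-reference"
        )
    logk = np.log(k[positive])
    log_geo = logk.mean(axis=1, keepdims=True)
    s = np.exp(np.median(logk - log_geo, axis=0))
    s = s / np.exp(np.mean(np.log(s)))  # geometric mean 1
    return pd.Series(s, index=counts.columns, name="size_factor")


@dataclass
class NBFit:
    """Mean-variance model for normalized counts.

    ``w_fit`` maps a normalized mean to the fitted variance of
    normalized counts (local regression across genes); the raw
    (overdispersion) variance is ``w - shot noise`` floored at zero, so
    the full fitted variance never falls below the mean.
    """

    factors: pd.Series
    _grid_q: np.ndarray = field(repr=False, default=None)
    _grid_w: np.ndarray = field(repr=False, default=None)
    _mean_inv_s: float = 0.0

    def w(self, q: np.ndarray) -> np.ndarray:
        """Fitted variance of normalized counts at normalized mean ``q``."""
        q = np.asarray(q, dtype=float)
        out = np.interp(np.log(np.maximum(q, 1e-12)), self._grid_q, self._grid_w)
        return np.exp(out)

    def raw_variance(self, q: np.ndarray) -> np.ndarray:
        """Fitted cross-replicate variance with sampling (shot) noise removed."""
        q = np.asarray(q, dtype=float)
        return np.maximum(self.w(q) - q * self._mean_inv_s, 0.0)


def fit_nb(counts: pd.DataFrame, conditions: np.ndarray, span: float = 0.3) -> NBFit:
    """Fit size factors and the mean-variance trend on a count table.

    ``conditions`` labels the columns; per-condition means and variances
    of normalized counts are pooled into one local (LOWESS) regression of
    log variance on log mean.
    """
    s = size_factors(counts)
    k = counts.to_numpy(dtype=float) / s.to_numpy()
    conditions = np.asarray(conditions)

    qs, ws = [], []
    for cond in np.unique(conditions):
        cols = conditions == cond
        m = int(cols.sum())
        if m < 2:
            continue
        sub = k[:, cols]
        # sample variances are chi^2_{m-1}-scaled: regressing their log
        # underestimates log sigma^2 by psi((m-1)/2) - log((m-1)/2);
        # add the analytic offset so the fitted trend is unbiased
        offset = np.log((m - 1) / 2) - digamma((m - 1) / 2)
        qs.append(sub.mean(axis=1))
        ws.append(np.log(np.where(sub.var(axis=1, ddof=1) > 0, sub.var(axis=1, ddof=1), np.nan)) + offset)
    q = np.concatenate(qs)
    logw = np.concatenate(ws)
    ok = (q > 0) & np.isfinite(logw)
    if ok.sum() < 10:
        raise ValueError("too few informative genes to fit a mean-variance trend")

    fitted = lowess(logw[ok], np.log(q[ok]), frac=span, return_sorted=True)
    grid_q, idx = np.unique(fitted[:, 0], return_index=True)
    fit = NBFit(factors=s)
    fit._grid_q = grid_q
    fit._grid_w = fitted[idx, 1]
    fit._mean_inv_s = float(np.mean(1.0 / s.to_numpy()))
    return fit


def _nb_pmf_grid(total: int, mu: float, var: float) -> np.ndarray:
    """pmf of a count on 0..total under NB (or Poisson when var <= mu)."""
    x = np.arange(total + 1)
    if var <= mu * (1 + 1e-9):
        return stats.poisson.pmf(x, mu)
    r = mu * mu / (var - mu)
    p = r / (r + mu)
    return stats.nbinom.pmf(x, r, p)


def nb_test(
    counts_a: pd.DataFrame, counts_b: pd.DataFrame, fit: NBFit | None = None
) -> pd.Series:
    """Per-gene two-sided exact NB test of condition totals.

    For each gene the split of the grand total between the two
    conditions is compared with its null distribution under independent
    NB sums whose means and variances follow the fitted mean-variance
    model at the pooled normalized mean.  Counts are rounded to integers
    for the exact test.  Genes with zero total get p = 1.
    """
    if counts_a.shape[1] < 2 or counts_b.shape[1] < 2:
        raise ValueError("need >=2 replicates per condition")
    joint = pd.concat([counts_a, counts_b], axis=1)
    conditions = np.array(["a"] * counts_a.shape[1] + ["b"] * counts_b.shape[1])
    if fit is None:
        fit = fit_nb(joint, conditions)

    s = fit.factors.to_numpy()
    s_a, s_b = s[: counts_a.shape[1]], s[counts_a.shape[1] :]
    ka = np.rint(counts_a.to_numpy(dtype=float))
    kb = np.rint(counts_b.to_numpy(dtype=float))

    norm_total = (ka / s_a).sum(axis=1) + (kb / s_b).sum(axis=1)
    q0 = norm_total / len(s)  # pooled normalized mean per gene
    v_raw = fit.raw_variance(q0)

    mu_a = q0 * s_a.sum()
    mu_b = q0 * s_b.sum()
    var_a = mu_a + v_raw * (s_a**2).sum()
    var_b = mu_b + v_raw * (s_b**2).sum()

    tot_a = ka.sum(axis=1).astype(int)
    tot_b = kb.sum(axis=1).astype(int)

    pvals = np.ones(len(joint))
    for i in range(len(joint)):
        ks = tot_a[i] + tot_b[i]
        if ks == 0:
            continue
        pa = _nb_pmf_grid(ks, mu_a[i], var_a[i])
        pb = _nb_pmf_grid(ks, mu_b[i], var_b[i])
        probs = pa * pb[::-1]  # P(A=a, B=ks-a) for a = 0..ks
        denom = probs.sum()
        if denom <= 0:
            continue
        obs = probs[tot_a[i]]
        pvals[i] = min(1.0, probs[probs <= obs * (1 + 1e-12)].sum() / denom)
    return pd.Series(pvals, index=joint.index, name="p")


def log2_fold_change(
    counts_m: pd.DataFrame, counts_g1: pd.DataFrame, fit: NBFit, pseudo: float = 0.5
) -> pd.Series:
    """Moderated log2 M/G1 fold-change on normalized counts."""
    s = fit.factors.to_numpy()
    s_m, s_g = s[: counts_m.shape[1]], s[counts_m.shape[1] :]
    qm = (counts_m.to_numpy(dtype=float) / s_m).mean(axis=1)
    qg = (counts_g1.to_numpy(dtype=float) / s_g).mean(axis=1)
    return pd.Series(
        np.log2((qm + pseudo) / (qg + pseudo)), index=counts_m.index, name="log2fc"
    )


@dataclass
class DESelection:
    """Per-gene DE statistics plus the selected gene set."""

    table: pd.DataFrame  # columns: statistic, p, q, log2fc, selected
    rule: str

    @property
    def selected(self) -> set[str]:
        return set(self.table.index[self.table["selected"]])


def select_top_fraction(
    pvalues: pd.Series, log2fc: pd.Series, frac: float = 0.10, rule: str = "top-fdr"
) -> DESelection:
    """Select the ``floor(frac * n)`` genes with smallest BH-adjusted p.

    Ties are broken deterministically by (q, |log2fc| descending,
    gene id).
    """
    if not np.isfinite(pvalues).all():
        raise ValueError("p-values must be finite")
    n_select = int(np.floor(frac * len(pvalues)))
    _, qvals, _, _ = multipletests(pvalues.to_numpy(), method="fdr_bh")
    tab = pd.DataFrame(
        {"p": pvalues, "q": qvals, "log2fc": log2fc.reindex(pvalues.index)}
    )
    ranked = tab.assign(absfc=tab["log2fc"].abs(), _id=tab.index.astype(str))
    ranked = ranked.sort_values(
        ["q", "absfc", "_id"], ascending=[True, False, True], kind="mergesort"
    )
    selected_ids = set(ranked.index[:n_select])
    tab["selected"] = tab.index.isin(selected_ids)
    tab["statistic"] = tab["p"]
    return DESelection(tab[["statistic", "p", "q", "log2fc", "selected"]], rule)


def anova_fc_select(
    intens_m: pd.DataFrame,
    intens_g1: pd.DataFrame,
    frac: float = 0.10,
    alpha: float = 0.05,
) -> DESelection:
    """DE selection for intensity data: ANOVA gate, then fold-change rank.

    A per-gene one-way ANOVA compares the M and G1 triplicates (log2
    intensities); among genes significant at ``alpha``, the genes with
    the largest |log2 M/G1 fold-change| are selected, up to
    ``floor(frac * n)`` of the tested universe.
    """
    common = intens_m.index.intersection(intens_g1.index)
    m = intens_m.loc[common].to_numpy(dtype=float)
    g = intens_g1.loc[common].to_numpy(dtype=float)
    with warnings.catch_warnings():
        # near-constant rows (e.g. fully imputed) are handled below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.f_oneway(m, g, axis=1)
    pvals = np.asarray(res.pvalue, dtype=float)
    degenerate = (m.std(axis=1) == 0) & (g.std(axis=1) == 0) & (m.mean(axis=1) == g.mean(axis=1))
    pvals[degenerate | ~np.isfinite(pvals)] = 1.0
    fstat = np.where(np.isfinite(res.statistic), res.statistic, 0.0)
    lfc = m.mean(axis=1) - g.mean(axis=1)  # log2-scale intensities

    tab = pd.DataFrame(
        {"statistic": fstat, "p": pvals, "q": pvals, "log2fc": lfc}, index=common
    )
    n_select = int(np.floor(frac * len(tab)))
    sig = tab[tab["p"] < alpha]
    ranked = sig.assign(absfc=sig["log2fc"].abs(), _id=sig.index.astype(str))
    ranked = ranked.sort_values(["absfc", "p", "_id"], ascending=[False, True, True])
    chosen = set(ranked.index[:n_select])
    tab["selected"] = tab.index.isin(chosen)
    return DESelection(tab[["statistic", "p", "q", "log2fc", "selected"]], "top-significant-fc")


@dataclass
class GeneSets:
    """The derived DE group structure of the two assays."""

    rp_de: set
    pp_de: set
    rp_only: set
    pp_only: set
    both: set
    union: set


def set_algebra(rp_de: set, pp_de: set) -> GeneSets:
    """RP-PP, PP-RP, RP∩PP and RP∪PP from the two DE selections."""
    rp_de, pp_de = set(rp_de), set(pp_de)
    return GeneSets(
        rp_de=rp_de,
        pp_de=pp_de,
        rp_only=rp_de - pp_de,
        pp_only=pp_de - rp_de,
        both=rp_de & pp_de,
        union=rp_de | pp_de,
    )


def hypergeom_overlap(set_a: set, set_b: set, universe: set) -> float:
    """Upper-tail hypergeometric p-value of the overlap |A ∩ B|."""
    set_a, set_b, universe = set(set_a), set(set_b), set(universe)
    if not set_a <= universe or not set_b <= universe:
        raise ValueError("sets must be subsets of the universe")
    k = len(set_a & set_b)
    return float(stats.hypergeom.sf(k - 1, len(universe), len(set_a), len(set_b)))


def opposite_direction_groups(
    fc_rp: pd.Series, fc_pp: pd.Series, significant: set | None = None
) -> tuple[set, set]:
    """Genes whose RP and PP M/G1 fold-changes disagree in sign.

    Group (a): RP fold-change > 0 and PP fold-change < 0; group (b) the
    reverse.  Restricted to ``significant`` genes when given (typically
    genes selected by both assays).
    """
    common = fc_rp.index.intersection(fc_pp.index)
    if significant is not None:
        common = common.intersection(pd.Index(sorted(significant)))
    rp = fc_rp.loc[common]
    pp = fc_pp.loc[common]
    group_a = set(common[(rp > 0) & (pp < 0)])
    group_b = set(common[(rp < 0) & (pp > 0)])
    return group_a, group_b
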