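"""Per-comparison differential expression with a moderated t-statistic.

Each probe gets a two-group equal-variance linear-model fit (log2 fold change
and pooled residual variance). The per-probe variances are then shrunk toward
a prior fitted across all probes of the comparison by empirical Bayes: the log
sample variances are moment-matched to a scaled F distribution, giving a prior
variance s0² with d0 prior degrees of freedom, and the posterior variance

    s²_post = (d0·s0² + df·s²) / (d0 + df)

replaces s² in the t statistic, which is referred to a t distribution with
d0 + df degrees of freedom. p-values are Benjamini–Hochberg adjusted across
the comparison's probes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .comparisons import ComparisonSpec
from .io_corpus import ExpressionMatrix

logger = logging.getLogger(__name__)

DE_COLUMNS = ["probe_id", "log2fc", "s2", "df", "t_mod", "p", "p_adj"]


@dataclass(frozen=True)
class EbayesPrior:
    """Shrinkage hyperparameters: prior df ``d0`` (may be ``inf``) and prior
    variance ``s0_2``."""

    d0: float
    s0_2: float

    def __post_init__(self) -> None:
        if not (self.d0 >= 0):
            raise ValueError("d0 must be >= 0 (math.inf for unbounded)")
        if not (self.s0_2 >= 0):
            raise ValueError("s0_2 must be >= 0")


def _trigamma(x: np.ndarray | float) -> np.ndarray | float:
    return special.polygamma(1, x)


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(_trigamma(x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if -dif / x < 1e-8:
            break
    return x


def fit_ebayes_prior(s2: np.ndarray, df: np.ndarray) -> EbayesPrior:
    """Moment-match log sample variances to estimate (d0, s0²).

    Uses the standard closed-form estimator: with z = log s², the residual
    moments of z − digamma(df/2) + log(df/2) identify the prior. A
    non-positive excess variance means the observed spread of variances is
    no wider than sampling noise, and d0 is taken as unbounded.
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.asarray(df, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0) & (df > 0)
    if ok.sum() < 2:
        pooled = float(np.nanmean(s2[np.isfinite(s2)])) if np.isfinite(s2).any() else 1.0
        return EbayesPrior(d0=math.inf, s0_2=max(pooled, np.finfo(float).tiny))
    z = np.log(s2[ok])
    dfo = df[ok]
    e = z - special.digamma(dfo / 2.0) + np.log(dfo / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(np.mean(_trigamma(dfo / 2.0)))
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        if not math.isfinite(d0):
            return EbayesPrior(d0=math.inf, s0_2=float(np.mean(s2[ok])))
        s0_2 = math.exp(
            emean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0)
        )
        return EbayesPrior(d0=d0, s0_2=s0_2)
    return EbayesPrior(d0=math.inf, s0_2=float(np.mean(s2[ok])))


def probe_de(
    matrix: ExpressionMatrix,
    comp: ComparisonSpec,
    prior: EbayesPrior | None = None,
) -> tuple[pd.DataFrame, EbayesPrior]:
    """Moderated two-group test for every probe of one comparison.

    Probes need >=2 non-missing samples per group; others are skipped. Fold
    change is mean(group_b) − mean(group_a) on the log2 scale. ``prior``
    overrides the fitted hyperparameters (d0=0 reproduces the ordinary pooled
    t-test). Returns the per-probe table and the prior used.
    """
    a = matrix.data[list(comp.samples_a)].to_numpy(dtype=float)
    b = matrix.data[list(comp.samples_b)].to_numpy(dtype=float)
    na = np.sum(~np.isnan(a), axis=1)
    nb = np.sum(~np.isnan(b), axis=1)
    testable = (na >= 2) & (nb >= 2)
    if not testable.any():
        logger.warning("%s: no testable probes", comp.comparison_id)
        return pd.DataFrame(columns=DE_COLUMNS), prior or EbayesPrior(math.inf, 1.0)

    probe_ids = np.asarray(matrix.probe_ids)[testable]
    a, b = a[testable], b[testable]
    na, nb = na[testable].astype(float), nb[testable].astype(float)

    mean_a = np.nanmean(a, axis=1)
    mean_b = np.nanmean(b, axis=1)
    log2fc = mean_b - mean_a
    ss = np.nansum((a - mean_a[:, None]) ** 2, axis=1) + np.nansum(
        (b - mean_b[:, None]) ** 2, axis=1
    )
    df = na + nb - 2.0
    s2 = ss / df

    if prior is None:
        prior = fit_ebayes_prior(s2, df)

    if math.isinf(prior.d0):
        s2_post = np.full_like(s2, prior.s0_2)
        df_total = np.full_like(df, np.inf)
    else:
        s2_post = (prior.d0 * prior.s0_2 + df * s2) / (prior.d0 + df)
        df_total = prior.d0 + df

    se2 = s2_post * (1.0 / na + 1.0 / nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = log2fc / np.sqrt(se2)
        # zero posterior variance: no evidence either way for a zero fold
        # change, overwhelming evidence otherwise
        t_mod = np.where(
            se2 == 0, np.where(log2fc == 0, 0.0, np.inf * np.sign(log2fc)), t_mod
        )
    finite_df = np.isfinite(df_total)
    p = np.empty_like(t_mod)
    p[finite_df] = 2.0 * stats.t.sf(np.abs(t_mod[finite_df]), df_total[finite_df])
    p[~finite_df] = 2.0 * stats.norm.sf(np.abs(t_mod[~finite_df]))

    out = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "log2fc": log2fc,
            "s2": s2,
            "df": df,
            "t_mod": t_mod,
            "p": p,
            "p_adj": bh_adjust(p),
        }
    )
    return out, prior


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def is_significant(
    p_adj, log2fc, alpha: float = 0.01, fc_threshold: float = 2.0
):
    """Adjusted p below ``alpha`` and |log2 fold change| at least
    log2(``fc_threshold``); works elementwise on arrays."""
    if not (0 < alpha <= 1):
        raise ValueError("alpha must be in (0, 1]")
    if fc_threshold < 1:
        raise ValueError("fc_threshold must be >= 1")
    return (np.asarray(p_adj) < alpha) & (
        np.abs(np.asarray(log2fc)) >= math.log2(fc_threshold)
    )
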