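"""Differential statistics shared by the RNA and ATAC arms.

Implements TMM between-sample normalization, log-CPM transformation,
expression filtering, an empirical-Bayes moderated t-test with
variance shrinkage, Benjamini-Hochberg adjustment, confident effect
sizes (the largest effect magnitude whose interval null is still
rejected after FDR control), the minimum-significant-distance ranking
statistic, and the signed inverse-normal gene score consumed by the
TF-activity stage.

All effect sizes are log2 fold changes (case minus control).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .io_formats import CountMatrix


@dataclass
class DifferentialResult:
    """Per-feature differential summary (effects in log2 units)."""

    feature_id: str
    log2fc: float
    ci_low: float
    ci_high: float
    p: float
    q: float
    confect: float | None = None
    msd: float | None = None


# ---------------------------------------------------------------------------
# TMM normalization
# ---------------------------------------------------------------------------


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, lib_obs: float, lib_ref: float,
              trim_m: float = 0.30, trim_a: float = 0.05) -> float:
    """Weighted trimmed mean of M-values for one sample against a reference.

    Genes with a zero count in either sample are excluded. M-values are
    trimmed 30% each tail, A-values 5% each tail; the surviving genes are
    averaged with inverse asymptotic-variance (delta-method) weights.
    Returns the log2 normalization factor.
    """
    keep = (obs > 0) & (ref > 0)
    obs, ref = obs[keep].astype(float), ref[keep].astype(float)
    if obs.size == 0:
        return 0.0
    p_obs, p_ref = obs / lib_obs, ref / lib_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    # inverse binomial variance weights
    w = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)

    finite = np.isfinite(m) & np.isfinite(a)
    m, a, w = m[finite], a[finite], w[finite]
    if m.size == 0:
        return 0.0
    if np.max(np.abs(m)) < 1e-6:  # identical relative profiles
        return 0.0

    n = m.size
    lo_m, hi_m = np.floor(n * trim_m) + 1, n + 1 - (np.floor(n * trim_m) + 1)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n + 1 - (np.floor(n * trim_a) + 1)
    rank_m = stats.rankdata(m)
    rank_a = stats.rankdata(a)
    keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not np.any(keep2):
        return 0.0
    f = np.sum(m[keep2] / w[keep2]) / np.sum(1.0 / w[keep2])
    return float(f) if np.isfinite(f) else 0.0


def tmm_factors(counts: CountMatrix | pd.DataFrame, ref: int | None = None) -> np.ndarray:
    """Trimmed-mean-of-M-values normalization factors, one per sample.

    The reference sample defaults to the one whose 75th-percentile
    count fraction is closest to the mean across samples. Factors are
    rescaled so their geometric mean is 1.
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    x = mat.to_numpy(dtype=float)
    if x.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    libs = x.sum(axis=0)
    zero = np.where(libs == 0)[0]
    if zero.size:
        raise ValueError(f"sample {mat.columns[zero[0]]!r} has all-zero counts")
    if ref is None:
        uq = np.array([np.quantile(x[x[:, j] > 0, j] / libs[j], 0.75)
                       if np.any(x[:, j] > 0) else 0.0
                       for j in range(x.shape[1])])
        ref = int(np.argmin(np.abs(uq - uq.mean())))
    log_f = np.array(
        [_tmm_pair(x[:, j], x[:, ref], libs[j], libs[ref]) for j in range(x.shape[1])]
    )
    factors = np.exp2(log_f)
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


def log_cpm(counts: CountMatrix | pd.DataFrame, factors: np.ndarray | None = None,
            prior: float = 0.5) -> pd.DataFrame:
    """log2 counts per million over TMM-effective library sizes."""
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    if prior <= 0:
        raise ValueError("prior must be > 0 (zero counts would give -inf)")
    if factors is None:
        factors = np.ones(mat.shape[1])
    libs = mat.to_numpy(dtype=float).sum(axis=0) * np.asarray(factors, dtype=float)
    vals = np.log2((mat.to_numpy(dtype=float) + prior) / libs[None, :] * 1e6)
    return pd.DataFrame(vals, index=mat.index, columns=mat.columns)


def filter_low_expression(counts: CountMatrix, min_count: float = 10,
                          min_samples: int | None = None) -> list[str]:
    """Features with adjusted count >= min_count in enough samples.

    ``min_count`` is scaled per sample by median-library size (a sample
    half the median library only needs half the counts); ``min_samples``
    defaults to the smallest condition group size.
    """
    mat = counts.counts
    libs = mat.to_numpy(dtype=float).sum(axis=0)
    med = np.median(libs)
    if min_samples is None:
        group_sizes = pd.Series(counts.conditions).value_counts()
        min_samples = int(group_sizes.min())
    if min_count <= 0:
        return list(mat.index)
    thresh = min_count * libs / med  # per-sample adjusted threshold
    ok = (mat.to_numpy(dtype=float) >= thresh[None, :]).sum(axis=1) >= min_samples
    return list(mat.index[ok])


# ---------------------------------------------------------------------------
# Moderated t-test with empirical-Bayes variance shrinkage
# ---------------------------------------------------------------------------


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (y > 0)."""
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-8 * x:
            break
    return float(x)


def _fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match log sample variances to a scaled F distribution.

    Returns (d0, s0_sq): the prior degrees of freedom and prior variance
    such that s2 ~ s0_sq * F(df, d0). d0 = inf when the observed spread
    of log s2 is no larger than expected from chi-square sampling alone.
    """
    ok = s2 > 0
    z = np.log(s2[ok])
    e_bias = special.digamma(df / 2) - np.log(df / 2)
    e = z - e_bias
    mean_e, var_e = float(np.mean(e)), float(np.var(e, ddof=1))
    excess = var_e - float(special.polygamma(1, df / 2))
    if excess <= 0:
        d0 = np.inf
        s0_sq = float(np.exp(mean_e))
    else:
        d0 = 2 * _trigamma_inverse(excess)
        s0_sq = float(np.exp(mean_e + special.digamma(d0 / 2) - np.log(d0 / 2)))
    return d0, s0_sq


def moderated_t_test(logexpr: pd.DataFrame, groups: list[str] | np.ndarray,
                     case: str | None = None, control: str | None = None,
                     alpha: float = 0.05) -> pd.DataFrame:
    """Two-group moderated t-test on a log-expression matrix.

    Per feature: ``log2fc = mean(case) - mean(control)``; the residual
    variance is shrunk towards a prior fitted by moment-matching the log
    sample variances to a scaled F distribution, and the t statistic uses
    the posterior variance on ``d0 + d_g`` degrees of freedom.

    Parameters
    ----------
    logexpr : DataFrame
        features x samples log2 expression.
    groups : sequence of str
        Two-level sample labels aligned with the columns.
    case, control : str
        Which level is the case (numerator). Default: first label seen is
        the control, the other the case.
    alpha : float
        1 - alpha confidence intervals.

    Returns a DataFrame indexed by feature with columns log2fc, ci_low,
    ci_high, p, q, se, df (q is BH over all features).
    """
    groups = np.asarray(groups)
    levels = list(dict.fromkeys(groups))
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 group levels, got {levels}")
    if control is None:
        control = levels[0]
    if case is None:
        case = next(l for l in levels if l != control)
    idx_case = groups == case
    idx_ctrl = groups == control
    n1, n2 = int(idx_case.sum()), int(idx_ctrl.sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 replicates per level")

    x = logexpr.to_numpy(dtype=float)
    xc, x0 = x[:, idx_case], x[:, idx_ctrl]
    lfc = xc.mean(axis=1) - x0.mean(axis=1)
    df_resid = n1 + n2 - 2
    ss = ((xc - xc.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (x0 - x0.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s2 = ss / df_resid
    if np.all(s2 == 0):
        raise ValueError("zero residual variance across all features (degenerate input)")

    d0, s0_sq = _fit_f_dist(s2, df_resid)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, lfc / se, 0.0)
    if np.isinf(df_total):
        p = 2 * stats.norm.sf(np.abs(t))
        crit = stats.norm.ppf(1 - alpha / 2)
    else:
        p = 2 * stats.t.sf(np.abs(t), df_total)
        crit = stats.t.ppf(1 - alpha / 2, df_total)
    q = bh_adjust(p)
    out = pd.DataFrame(
        {
            "log2fc": lfc,
            "ci_low": lfc - crit * se,
            "ci_high": lfc + crit * se,
            "p": p,
            "q": q,
            "se": se,
        },
        index=logexpr.index,
    )
    out.attrs["df_total"] = df_total
    out.attrs["d0"] = d0
    out.attrs["s0_sq"] = s0_sq
    out["df"] = df_total
    return out


def bh_adjust(p: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Confident effect sizes (interval-null / TREAT with BH)
# ---------------------------------------------------------------------------


def _treat_p(lfc: np.ndarray, se: np.ndarray, df: float, c: np.ndarray | float) -> np.ndarray:
    """Two-sided p-value for the interval null |beta| <= c.

    Uses the moderated t reference: with tau = |lfc|/se and delta = c/se,
    p = P(T > tau - delta) + P(T > tau + delta).
    """
    tau = np.abs(lfc) / se
    delta = np.asarray(c, dtype=float) / se
    if np.isinf(df):
        sf = stats.norm.sf
    else:
        sf = lambda v: stats.t.sf(v, df)  # noqa: E731
    return np.minimum(sf(tau - delta) + sf(tau + delta), 1.0)


def _bh_rejected(p: np.ndarray, level: float) -> np.ndarray:
    q = bh_adjust(p)
    return q < level


def confident_effect(results: pd.DataFrame, fdr_level: float = 0.05,
                     tol: float = 1e-4) -> pd.Series:
    """Largest effect bound per feature still rejected under BH at fdr_level.

    For each feature the interval null H0: |beta| <= c is tested with the
    moderated t reference (TREAT-style p); ``confect`` is the largest c at
    which the feature is still BH-rejected at ``fdr_level`` across all
    features, signed by the feature's log2fc. Features not rejected even
    at c = 0 (q >= fdr_level) get NaN.

    ``results`` must come from :func:`moderated_t_test` (needs log2fc, se,
    df, p columns). Monotone bisection to ``tol`` log2 units.
    """
    lfc = results["log2fc"].to_numpy(dtype=float)
    se = results["se"].to_numpy(dtype=float)
    df = float(results["df"].iloc[0])

    base_reject = _bh_rejected(_treat_p(lfc, se, df, 0.0), fdr_level)
    confect = np.full(lfc.size, np.nan)
    idx = np.where(base_reject)[0]
    if idx.size == 0:
        return pd.Series(confect, index=results.index, name="confect")

    lo = np.zeros(idx.size)
    hi = np.abs(lfc[idx]).copy()
    # a feature rejected at c = |lfc| would get confect = |lfc| exactly
    at_hi = np.array(
        [_bh_rejected(_treat_p(lfc, se, df, c), fdr_level)[g] for g, c in zip(idx, hi)]
    )
    lo = np.where(at_hi, hi, lo)
    n_iter = max(1, int(np.ceil(np.log2(max(np.max(hi), tol) / tol))))
    for _ in range(n_iter):
        active = ~at_hi & (hi - lo > tol)
        if not np.any(active):
            break
        mid = 0.5 * (lo + hi)
        for k in np.where(active)[0]:
            g = idx[k]
            if _bh_rejected(_treat_p(lfc, se, df, mid[k]), fdr_level)[g]:
                lo[k] = mid[k]
            else:
                hi[k] = mid[k]
    confect[idx] = np.sign(lfc[idx]) * lo
    return pd.Series(confect, index=results.index, name="confect")


# ---------------------------------------------------------------------------
# Ranking transforms
# ---------------------------------------------------------------------------


def msd_rank(results: pd.DataFrame) -> pd.DataFrame:
    """Minimum significant distance: the CI bound nearest zero, signed.

    ``msd = ci_low`` for positive effects, ``-ci_high`` for negative;
    negative msd means the CI crosses zero. Returns the input with an
    ``msd`` column, sorted by decreasing msd (ties broken by feature id).
    """
    lfc = results["log2fc"].to_numpy(dtype=float)
    msd = np.where(lfc > 0, results["ci_low"].to_numpy(dtype=float),
                   -results["ci_high"].to_numpy(dtype=float))
    out = results.copy()
    out["msd"] = msd
    ids = out.index.to_numpy(dtype=object)
    order = np.lexsort((ids, -msd))  # decreasing msd, then feature id
    return out.iloc[order]


def signed_quantile_score(q: np.ndarray | pd.Series,
                          log2fc: np.ndarray | pd.Series) -> np.ndarray:
    """Signed inverse-normal transform of BH-adjusted p-values.

    ``z = sign(log2fc) * Phi^{-1}(1 - q/2)``; q = 1 maps to 0. q must be
    floored away from 0 by the caller (q = 0 would be infinite).
    """
    q = np.asarray(q, dtype=float)
    lfc = np.asarray(log2fc, dtype=float)
    if np.any(q <= 0):
        raise ValueError("q-values must be > 0 (floor them before scoring)")
    if np.any(q > 1):
        raise ValueError("q-values must be <= 1")
    return np.sign(lfc) * stats.norm.ppf(1 - q / 2)


# ---------------------------------------------------------------------------
# End-to-end per-assay convenience
# ---------------------------------------------------------------------------


def run_differential(counts: CountMatrix, case: str, control: str,
                     fdr_level: float = 0.05, do_filter: bool = True) -> pd.DataFrame:
    """Filter, normalize, test and annotate one case-vs-control contrast.

    Returns a DataFrame with log2fc, ci_low, ci_high, p, q, se, df,
    confect and msd, sorted by decreasing msd.
    """
    keep_samples = [s for s in counts.samples
                    if counts.conditions[s] in (case, control)]
    sub = CountMatrix(
        counts.counts[keep_samples],
        {s: counts.conditions[s] for s in keep_samples},
        {s: counts.replicates[s] for s in keep_samples},
    )
    if do_filter:
        kept = filter_low_expression(sub)
        sub = CountMatrix(sub.counts.loc[kept], sub.conditions, sub.replicates)
    factors = tmm_factors(sub)
    expr = log_cpm(sub, factors)
    groups = [sub.conditions[s] for s in sub.samples]
    res = moderated_t_test(expr, groups, case=case, control=control, alpha=fdr_level)
    res["confect"] = confident_effect(res, fdr_level=fdr_level)
    return msd_rank(res)
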