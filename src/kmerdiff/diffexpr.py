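"""Median-of-ratios normalization and per-feature differential testing.

Normalization follows the classic pseudo-reference construction: the
pseudo-reference count of a feature is its geometric mean across samples,
and a sample's size factor is the median over features of the ratio of the
sample count to the pseudo-reference count. Features with a zero count in
any sample are excluded from size-factor estimation (their geometric mean
is zero); if no all-positive feature exists, a documented fallback uses
each feature's geometric mean over its nonzero entries.

Testing is a moderated t on log2(x + c): per-feature pooled variances are
shrunk toward a common prior estimated by matching the moments of
log(sample variances) to a scaled-F model (empirical Bayes with
moment-matched prior degrees of freedom d0 and prior variance s0^2). A
plain Welch t mode is available for cross-checking. Fold changes are
log2((mean_tumor + c) / (mean_normal + c)) with pseudocount c = 0.5.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .kmers import KmerCountMatrix

_P_FLOOR = 1e-300


def size_factors(M) -> pd.Series:
    """Median-of-ratios size factor per sample.

    Accepts a :class:`KmerCountMatrix` or a plain counts DataFrame. A single
    sample gets size factor 1.
    """
    df = M.counts if isinstance(M, KmerCountMatrix) else M
    if df.shape[1] == 1:
        return pd.Series(1.0, index=df.columns)
    x = df.to_numpy(dtype=float)
    all_pos = (x > 0).all(axis=1)
    if all_pos.any():
        logs = np.log(x[all_pos])
        geo = logs.mean(axis=1)
        ratios = logs - geo[:, None]
    else:
        warnings.warn(
            "no feature has positive counts in every sample; falling back to "
            "geometric means over nonzero entries",
            stacklevel=2,
        )
        with np.errstate(divide="ignore"):
            logs = np.log(x)
        any_pos = (x > 0).any(axis=1)
        if not any_pos.any():
            return pd.Series(1.0, index=df.columns)
        logs = logs[any_pos]
        geo = np.array(
            [row[np.isfinite(row)].mean() for row in logs]
        )
        ratios = np.where(np.isfinite(logs), logs - geo[:, None], np.nan)
    s = np.exp(np.nanmedian(ratios, axis=0))
    return pd.Series(s, index=df.columns)


def normalize(M: KmerCountMatrix, s: pd.Series) -> KmerCountMatrix:
    """Divide each sample column by its size factor."""
    if len(s) != M.n_samples:
        raise ValueError("size factor vector length does not match sample count")
    if (np.asarray(s, dtype=float) <= 0).any():
        raise ValueError("size factors must be positive")
    return KmerCountMatrix(
        counts=M.counts / s.reindex(M.samples),
        k=M.k,
        conditions=M.conditions,
        size_factors=pd.Series(np.asarray(s, dtype=float), index=M.samples),
    )


def _trigamma_inverse(y: float) -> float:
    # Newton iteration for x with trigamma(x) = y (cf. limma::trigammaInverse)
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_variance_prior(s2: np.ndarray, df: float):
    """Moment-match a scaled inverse-chi-square prior to sample variances.

    Returns (d0, s0^2): prior degrees of freedom (possibly inf) and prior
    variance, using the moments of log(s2) (Smyth-style closed form).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0)
    if ok.sum() < 2:
        return np.inf, float(np.median(s2[ok])) if ok.any() else 0.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    ebar = float(e.mean())
    n = e.size
    evar = float(((e - ebar) ** 2).sum() / (n - 1))
    evar -= float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s02 = float(np.exp(ebar + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        # no excess spread beyond sampling noise: complete shrinkage to the
        # common variance (its maximum-likelihood estimate, the plain mean)
        d0 = np.inf
        s02 = float(s2[ok].mean())
    return d0, s02


def moderated_ttest(logx: np.ndarray, is_a: np.ndarray):
    """Two-group moderated t over rows of ``logx``.

    ``is_a`` marks group-A (tumor) columns. Returns (delta, t, pvalue, d0,
    s2_post) with delta = mean_A - mean_B on the log scale.
    """
    a = logx[:, is_a]
    b = logx[:, ~is_a]
    n1, n2 = a.shape[1], b.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("moderated t needs >=2 samples per group")
    df = n1 + n2 - 2
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    ss = ((a - ma[:, None]) ** 2).sum(axis=1) + ((b - mb[:, None]) ** 2).sum(axis=1)
    s2 = ss / df
    d0, s02 = fit_variance_prior(s2, df)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s02)
        df_total = np.inf
    else:
        s2_post = (d0 * s02 + df * s2) / (d0 + df)
        df_total = d0 + df
    delta = ma - mb
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, delta / np.where(se > 0, se, 1.0), 0.0)
        t = np.where((se == 0) & (delta != 0), np.inf * np.sign(delta), t)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.clip(p, _P_FLOOR, 1.0)
    return delta, t, p, d0, s2_post


def differential_test(
    M,
    conditions: pd.Series | None = None,
    method: str = "moderated",
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-feature tumor-vs-normal differential test.

    ``M`` is a (normalized) :class:`KmerCountMatrix` or a plain DataFrame
    (features x samples) with ``conditions`` giving 'tumor'/'normal' per
    sample. Returns a DataFrame with baseMeanN, baseMeanT, log2FC (tumor
    over normal, pseudocounted) and pvalue.
    """
    if isinstance(M, KmerCountMatrix):
        df, conditions = M.counts, M.conditions
    else:
        df = M
        if conditions is None:
            raise ValueError("conditions required with a plain DataFrame")
    conditions = conditions.reindex(df.columns)
    is_t = (conditions == "tumor").to_numpy()
    is_n = (conditions == "normal").to_numpy()
    if is_t.sum() < 2 or is_n.sum() < 2:
        raise ValueError("differential testing needs >=2 samples per condition")
    x = df.to_numpy(dtype=float)[:, is_t | is_n]
    grp = is_t[is_t | is_n]
    mean_t = x[:, grp].mean(axis=1)
    mean_n = x[:, ~grp].mean(axis=1)
    c = pseudocount
    log2fc = np.log2((mean_t + c) / (mean_n + c))
    logx = np.log2(x + c)
    if method == "moderated":
        _, _, p, _, _ = moderated_ttest(logx, grp)
    elif method == "welch":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = stats.ttest_ind(logx[:, grp], logx[:, ~grp], axis=1, equal_var=False)
        ldiff = logx[:, grp].mean(axis=1) - logx[:, ~grp].mean(axis=1)
        # NaN arises only for zero variance in both groups: p=1 when the
        # means agree, overwhelming evidence when they do not
        p = np.where(
            np.isnan(res.pvalue),
            np.where(np.abs(ldiff) < 1e-12, 1.0, _P_FLOOR),
            res.pvalue,
        )
        p = np.clip(p, _P_FLOOR, 1.0)
    else:
        raise ValueError(f"unknown test method {method!r}")
    # zero difference on both scales is never evidence; keep p = 1 there
    same = (mean_t == mean_n) & (np.abs(logx[:, grp].mean(axis=1) - logx[:, ~grp].mean(axis=1)) < 1e-12)
    p = np.where(same, 1.0, p)
    return pd.DataFrame(
        {
            "baseMeanN": mean_n,
            "baseMeanT": mean_t,
            "log2FC": log2fc,
            "pvalue": p,
        },
        index=df.index,
    )


def adjust_pvalues(p, method: str = "bh") -> np.ndarray:
    """Multiple-testing adjustment: 'bh' (step-up FDR), 'bonferroni' or 'none'."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if method == "none":
        return p.copy()
    key = {"bh": "fdr_bh", "bonferroni": "bonferroni"}.get(method)
    if key is None:
        raise ValueError(f"unknown adjustment method {method!r}")
    return multipletests(p, method=key)[1]


def test_feature(x_tumor, x_normal, pseudocount: float = 0.5):
    """Fold change and p-value for a single feature.

    log2FC is always returned; the p-value is a two-sided Welch t on
    log2(x + c) and is NaN (flagged undefined) when either group has fewer
    than 2 samples. Ensemble variance shrinkage needs many features, so the
    single-feature path uses the plain t; see :func:`differential_test` for
    the moderated matrix path.
    """
    xt = np.asarray(x_tumor, dtype=float)
    xn = np.asarray(x_normal, dtype=float)
    c = pseudocount
    log2fc = float(np.log2((xt.mean() + c) / (xn.mean() + c)))
    if len(xt) < 2 or len(xn) < 2:
        return log2fc, float("nan")
    lt, ln = np.log2(xt + c), np.log2(xn + c)
    if lt.var() == 0 and ln.var() == 0:
        # degenerate constant groups: no evidence if equal, unbounded if not
        return log2fc, 1.0 if np.isclose(lt.mean(), ln.mean()) else _P_FLOOR
    res = stats.ttest_ind(lt, ln, equal_var=False)
    p = 1.0 if np.isnan(res.pvalue) else float(res.pvalue)
    return log2fc, float(np.clip(p, _P_FLOOR, 1.0))


def select_significant(
    results: pd.DataFrame,
    alpha: float = 0.05,
    min_abs_log2fc: float = 1.0,
    use_adjusted: bool = True,
    adjust: str = "bh",
) -> pd.DataFrame:
    """Keep features passing the significance and fold-change thresholds.

    Adds ``padj`` (if absent) and a ``direction`` ('up'/'down') column; the
    fold-change filter is two-sided (|log2FC| > threshold).
    """
    if alpha <= 0 or min_abs_log2fc < 0:
        raise ValueError("thresholds must be positive")
    out = results.copy()
    if "padj" not in out.columns:
        out["padj"] = adjust_pvalues(out["pvalue"].to_numpy(), method=adjust)
    crit = out["padj"] if use_adjusted else out["pvalue"]
    keep = (crit < alpha) & (out["log2FC"].abs() > min_abs_log2fc)
    out = out.loc[keep].copy()
    out["direction"] = np.where(out["log2FC"] > 0, "up", "down")
    return out
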