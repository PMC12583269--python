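"""Two-group differential expression with an empirical-Bayes moderated t.

Expression is log2(nRPM + 1).  For each gene a two-group comparison gives a
pooled residual variance s_g^2 on d = n1 + n2 - 2 degrees of freedom; an
inverse-chi-square prior (d0, s0^2) is estimated by moment matching on
log s_g^2 and the posterior variance

    s~_g^2 = (d0 * s0^2 + d * s_g^2) / (d0 + d)

shrinks each gene toward the common value.  The moderated t uses s~_g and
d0 + d degrees of freedom; Benjamini-Hochberg adjustment is applied across
all tested genes, and a gene is called differentially expressed when
adj_p < 0.05 and |log2 fold change| >= 0.5.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "log_transform",
    "benjamini_hochberg",
    "moderated_t_contrast",
    "zscore_rows",
    "volcano_table",
    "DEG_ADJ_P",
    "DEG_ABS_LOG2FC",
]

DEG_ADJ_P = 0.05
DEG_ABS_LOG2FC = 0.5


def log_transform(nrpm: np.ndarray) -> np.ndarray:
    """log2(nRPM + 1), elementwise; rejects negative input."""
    nrpm = np.asarray(nrpm, dtype=float)
    if np.any(nrpm < 0):
        raise ValueError("nRPM values must be non-negative")
    return np.log2(nrpm + 1.0)


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """Step-up BH adjusted p-values, returned in the input order."""
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y (Newton on the standard expansion)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if abs(dif / y) < 1e-10:
            break
    return float(y)


def _estimate_prior(s2: np.ndarray, d: float) -> tuple[float, float]:
    """Moment-match the scaled inverse-chi-square prior on log variances.

    Returns (d0, s0^2); d0 = inf when the observed log-variance spread is no
    larger than sampling alone predicts.
    """
    z = np.log(s2)
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, d / 2.0)
    if evar <= 0:
        return np.inf, float(np.exp(emean))
    d0 = 2.0 * _trigamma_inverse(evar)
    s0_sq = np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    return float(d0), float(s0_sq)


def moderated_t_contrast(
    expr: pd.DataFrame,
    high: np.ndarray,
    prior_df: float | None = None,
    prior_var: float | None = None,
    gene_class: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-gene moderated-t contrast of the high group vs the rest.

    ``expr`` is samples x genes log2 expression; ``high`` a boolean vector
    over samples.  ``prior_df`` overrides the estimated d0 (0 recovers the
    ordinary pooled t; ``inf`` the s0-based z) and ``prior_var`` pins s0^2
    (otherwise moment-matched given d0).  Genes constant in both groups are
    flagged (``zero_variance``) and excluded from testing.
    """
    high = np.asarray(high, dtype=bool)
    if high.shape[0] != expr.shape[0]:
        raise ValueError("group labels must match the number of samples")
    n1, n2 = int(high.sum()), int((~high).sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need at least 2 samples")
    if expr.shape[1] < 2:
        raise ValueError("need at least 2 genes")

    x = expr.to_numpy(dtype=float)
    m1 = x[high].mean(axis=0)
    m2 = x[~high].mean(axis=0)
    v1 = x[high].var(axis=0, ddof=1)
    v2 = x[~high].var(axis=0, ddof=1)
    d = n1 + n2 - 2
    s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / d
    log2_fc = m1 - m2
    zero_var = s2 <= 0

    testable = ~zero_var
    if not testable.any():
        raise ValueError("every gene has zero pooled variance")
    if prior_df is None:
        d0, s0_sq = _estimate_prior(s2[testable], d)
    elif prior_df == 0:
        d0, s0_sq = 0.0, 1.0  # s0 unused when d0 = 0
    elif np.isinf(prior_df):
        d0, s0_sq = np.inf, float(np.exp(np.log(s2[testable]).mean()))
    else:
        # moment-match s0^2 conditionally on the supplied d0
        d0 = float(prior_df)
        e = np.log(s2[testable]) - special.digamma(d / 2.0) + np.log(d / 2.0)
        s0_sq = float(np.exp(e.mean() + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    if prior_var is not None:
        s0_sq = float(prior_var)

    scale = np.sqrt(1.0 / n1 + 1.0 / n2)
    if np.isinf(d0):
        post_s2 = np.full(s2.shape, s0_sq)
        df_total = np.inf
    else:
        post_s2 = (d0 * s0_sq + d * s2) / (d0 + d)
        df_total = d0 + d
    with np.errstate(divide="ignore", invalid="ignore"):
        t = log2_fc / (np.sqrt(post_s2) * scale)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    adj = np.full(p.shape, np.nan)
    adj[testable] = benjamini_hochberg(p[testable])

    result = pd.DataFrame(
        {
            "gene": expr.columns,
            "log2_fc": log2_fc,
            "moderated_t": np.where(testable, t, np.nan),
            "p_value": np.where(testable, p, np.nan),
            "adj_p": adj,
            "zero_variance": zero_var,
        }
    )
    result["is_deg"] = (
        (result["adj_p"] < DEG_ADJ_P) & (result["log2_fc"].abs() >= DEG_ABS_LOG2FC)
    ).fillna(False)
    result["gene_class"] = [
        (gene_class or {}).get(g, "other") for g in expr.columns
    ]
    result.attrs["prior_df"] = d0
    result.attrs["prior_var"] = s0_sq
    return result


def zscore_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Row-standardize a genes x samples matrix; constant rows become NaN."""
    arr = matrix.to_numpy(dtype=float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (arr - mean) / sd
    z[np.repeat(sd == 0, arr.shape[1], axis=1)] = np.nan
    return pd.DataFrame(z, index=matrix.index, columns=matrix.columns)


def volcano_table(results: pd.DataFrame) -> pd.DataFrame:
    """Volcano-plot data: -log10 adjusted p vs log2 fold change, with the
    gene-class labels and the DEG significance flag."""
    if results.empty:
        raise ValueError("empty contrast results")
    out = results.copy()
    out["neg_log10_adj_p"] = -np.log10(out["adj_p"])
    return out[["gene", "log2_fc", "neg_log10_adj_p", "gene_class", "is_deg"]]
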