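"""Somatic-mutation enrichment between expression-defined groups.

Gene-level and pathway-level (hallmark-style gene set) alteration
frequencies are contrasted between the high and low/moderate groups with
Fisher's exact test; Benjamini-Hochberg q-values are computed within each
analysis, and a feature is significant when q < 0.05 and |log2 OR| > 1.
A separate top-k comparison mirrors the classic landscape figure: the union
of each group's k most frequently altered genes is tested per gene against
a Bonferroni threshold of 0.05 / union size.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .contrast import benjamini_hochberg

__all__ = [
    "FisherResult",
    "EnrichmentResult",
    "fisher_exact_2x2",
    "gene_level_enrichment",
    "pathway_collapse",
    "pathway_level_enrichment",
    "bonferroni_topk_comparison",
    "SIG_Q",
    "SIG_ABS_LOG2_OR",
]

SIG_Q = 0.05
SIG_ABS_LOG2_OR = 1.0


@dataclass
class FisherResult:
    p_value: float
    odds_ratio: float
    corrected: bool        # Haldane-Anscombe +0.5 applied
    degenerate: bool = False  # zero margin: p = 1, OR undefined


@dataclass
class EnrichmentResult:
    feature: str
    level: str  # "gene" or "pathway"
    counts: tuple[int, int, int, int]  # altered_high, total_high, altered_ref, total_ref
    odds_ratio: float
    log2_or: float
    p_value: float
    q_value: float
    significant: bool
    direction: str  # "high" or "low_moderate"


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> FisherResult:
    """Two-sided Fisher's exact test plus a cross-product odds ratio.

    The two-sided p sums hypergeometric point probabilities no larger than
    the observed one.  A zero cell gets the Haldane-Anscombe +0.5 odds-ratio
    correction (flagged); a zero margin returns p = 1 with an undefined OR.
    """
    cells = (a, b, c, d)
    if any((not float(x).is_integer()) or x < 0 for x in cells):
        raise ValueError("cells must be non-negative integers")
    if sum(cells) == 0:
        raise ValueError("empty table")
    if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
        return FisherResult(p_value=1.0, odds_ratio=math.nan, corrected=False, degenerate=True)
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    corrected = any(x == 0 for x in cells)
    if corrected:
        a_, b_, c_, d_ = (x + 0.5 for x in cells)
    else:
        a_, b_, c_, d_ = cells
    return FisherResult(p_value=float(p), odds_ratio=(a_ * d_) / (b_ * c_), corrected=corrected)


def _enrich(
    altered: pd.DataFrame, high: np.ndarray, level: str, min_altered: int
) -> list[EnrichmentResult]:
    high = np.asarray(high, dtype=bool)
    if high.shape[0] != altered.shape[0]:
        raise ValueError("group labels must match the mutation matrix rows")
    n_high = int(high.sum())
    n_ref = int((~high).sum())
    if n_high == 0 or n_ref == 0:
        raise ValueError("both groups must be non-empty")

    arr = altered.to_numpy(dtype=int)
    totals = arr.sum(axis=0)
    keep = totals >= min_altered
    if not keep.any():
        raise ValueError(f"no {level} passes the min_altered={min_altered} filter")

    features = [f for f, k in zip(altered.columns, keep) if k]
    raw = []
    for j, f in zip(np.flatnonzero(keep), features):
        a = int(arr[high, j].sum())
        c = int(arr[~high, j].sum())
        fr = fisher_exact_2x2(a, n_high - a, c, n_ref - c)
        raw.append((f, a, c, fr))
    q = benjamini_hochberg(np.array([fr.p_value for *_, fr in raw]))
    results = []
    for (f, a, c, fr), qv in zip(raw, q):
        log2_or = math.log2(fr.odds_ratio) if fr.odds_ratio > 0 else -math.inf
        results.append(
            EnrichmentResult(
                feature=f,
                level=level,
                counts=(a, n_high, c, n_ref),
                odds_ratio=fr.odds_ratio,
                log2_or=log2_or,
                p_value=fr.p_value,
                q_value=float(qv),
                significant=bool(qv < SIG_Q and abs(log2_or) > SIG_ABS_LOG2_OR),
                direction="high" if log2_or > 0 else "low_moderate",
            )
        )
    return results


def gene_level_enrichment(
    mutations: pd.DataFrame, high: np.ndarray, min_altered: int = 3
) -> list[EnrichmentResult]:
    """Per-gene Fisher enrichment (genes altered in >= min_altered samples)."""
    return _enrich(mutations, high, "gene", min_altered)


def pathway_collapse(
    mutations: pd.DataFrame, sets: dict[str, list[str]], min_members: int = 1
) -> pd.DataFrame:
    """Collapse gene mutations to sample x pathway indicators.

    A pathway is altered in a sample when at least ``min_members`` member
    genes are altered; sets with no gene in the matrix are dropped with a
    warning.
    """
    cols = {}
    for name, members in sets.items():
        overlap = [g for g in members if g in mutations.columns]
        if not overlap:
            warnings.warn(f"gene set {name!r} has no overlap with the mutation matrix; dropped")
            continue
        cols[name] = (mutations[overlap].sum(axis=1) >= min_members).astype(int)
    if not cols:
        raise ValueError("no gene set overlaps the mutation matrix")
    return pd.DataFrame(cols, index=mutations.index)


def pathway_level_enrichment(
    collapsed: pd.DataFrame, high: np.ndarray, min_altered: int = 1
) -> list[EnrichmentResult]:
    """Pathway-level Fisher enrichment over the collapsed indicator matrix."""
    return _enrich(collapsed, high, "pathway", min_altered)


def bonferroni_topk_comparison(
    mutations: pd.DataFrame, high: np.ndarray, k: int = 20
) -> tuple[pd.DataFrame, float]:
    """Fisher tests over the union of each group's top-k altered genes.

    Ties at rank k are broken by frequency descending, then gene name
    ascending.  The Bonferroni threshold is 0.05 / union size.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    high = np.asarray(high, dtype=bool)
    n_high = int(high.sum())
    n_ref = int((~high).sum())
    if k > mutations.shape[1]:
        warnings.warn(f"k={k} exceeds the {mutations.shape[1]} available genes; truncated")
        k = mutations.shape[1]

    freq_high = mutations.loc[high].mean(axis=0)
    freq_ref = mutations.loc[~high].mean(axis=0)

    def _topk(freq: pd.Series) -> list[str]:
        ranked = sorted(freq.items(), key=lambda kv: (-kv[1], kv[0]))
        return [g for g, _ in ranked[:k]]

    union = sorted(set(_topk(freq_high)) | set(_topk(freq_ref)))
    threshold = 0.05 / len(union)
    rows = []
    for g in union:
        a = int(mutations.loc[high, g].sum())
        c = int(mutations.loc[~high, g].sum())
        fr = fisher_exact_2x2(a, n_high - a, c, n_ref - c)
        rows.append(
            {
                "gene": g,
                "freq_high": freq_high[g],
                "freq_low_moderate": freq_ref[g],
                "p_value": fr.p_value,
                "odds_ratio": fr.odds_ratio,
                "significant": fr.p_value < threshold,
            }
        )
    table = pd.DataFrame(rows)
    table.attrs["union_size"] = len(union)
    table.attrs["threshold"] = threshold
    return table, threshold
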