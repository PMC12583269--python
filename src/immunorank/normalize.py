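"""nRPM normalization and reference-cohort percentile ranking.

Targeted immune-panel read counts are normalized in two steps before any
cross-sample comparison:

1. **Background subtraction** — each batch carries a no-template control
   (NTC); its per-gene counts are subtracted (floored at zero) from every
   sample in that batch.
2. **Housekeeping normalization** — background-subtracted counts are scaled
   to reads per million (RPM), and the median ratio of the sample's ten
   housekeeping-gene RPMs against a locked housekeeping RPM profile gives a
   sample-specific Normalization Ratio.  Dividing the sample's RPM values by
   that ratio yields nRPM.

Each gene's nRPM is then converted to a percentile rank (0-100) against the
locked reference cohort's nRPM distribution for that gene, and ranks are
categorized as low (<25), moderate (25-<75), or high (>=75).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CATEGORY_LOW",
    "CATEGORY_MODERATE",
    "CATEGORY_HIGH",
    "HIGH_CUTOFF",
    "LOW_CUTOFF",
    "ZeroDepthError",
    "DegenerateReferenceError",
    "QCFailure",
    "RawPanelCounts",
    "ReferenceModel",
    "PercentileProfile",
    "subtract_background",
    "to_rpm",
    "normalization_ratio",
    "compute_nrpm",
    "percentile_rank",
    "percentile_rank_vector",
    "categorize",
    "categorize_vector",
    "build_reference_model",
    "percentile_table",
]

CATEGORY_LOW = "low"
CATEGORY_MODERATE = "moderate"
CATEGORY_HIGH = "high"
HIGH_CUTOFF = 75.0
LOW_CUTOFF = 25.0


class ZeroDepthError(ValueError):
    """Raised when a sample has zero background-subtracted reads."""


class DegenerateReferenceError(ValueError):
    """Raised when a reference gene has fewer than two distinct nRPM values."""


@dataclass(frozen=True)
class QCFailure:
    """A sample excluded by normalization QC, with the reason."""

    sample_id: str
    reason: str


@dataclass
class RawPanelCounts:
    """Integer read counts for samples x genes plus per-batch NTC vectors."""

    sample_ids: list[str]
    gene_ids: list[str]
    counts: np.ndarray
    batch_of: dict[str, str]
    ntc_of: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        n, g = self.counts.shape
        if n != len(self.sample_ids) or g != len(self.gene_ids):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.gene_ids)} genes"
            )
        if np.any(self.counts < 0):
            raise ValueError("read counts must be non-negative")
        for sid in self.sample_ids:
            batch = self.batch_of.get(sid)
            if batch is None:
                raise ValueError(f"sample {sid!r} has no batch label")
            if batch not in self.ntc_of:
                raise ValueError(f"batch {batch!r} has no NTC vector")
        for batch, vec in self.ntc_of.items():
            vec = np.asarray(vec)
            if vec.shape != (g,):
                raise ValueError(f"NTC vector for batch {batch!r} has wrong length")
            if np.any(vec < 0):
                raise ValueError("NTC counts must be non-negative")
            self.ntc_of[batch] = vec

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def row(self, sample_id: str) -> np.ndarray:
        return self.counts[self.sample_ids.index(sample_id)]

    def ntc_for(self, sample_id: str) -> np.ndarray:
        return self.ntc_of[self.batch_of[sample_id]]


@dataclass
class ReferenceModel:
    """Locked housekeeping RPM profile and per-gene reference nRPM vectors."""

    hk_genes: list[str]
    hk_rpm_profile: dict[str, float]
    reference_nrpm: dict[str, np.ndarray]
    reference_size: int

    def __post_init__(self) -> None:
        if len(self.hk_genes) != 10:
            raise ValueError(f"expected 10 housekeeping genes, got {len(self.hk_genes)}")
        for g in self.hk_genes:
            if self.hk_rpm_profile.get(g, 0.0) <= 0:
                raise ValueError(f"housekeeping profile for {g!r} must be > 0")
        for g, vec in self.reference_nrpm.items():
            vec = np.asarray(vec, dtype=float)
            if len(vec) != self.reference_size:
                raise ValueError(f"reference vector for {g!r} has wrong length")
            if np.any(np.diff(vec) < 0):
                raise ValueError(f"reference vector for {g!r} is not sorted")
            self.reference_nrpm[g] = vec

    @property
    def gene_ids(self) -> list[str]:
        return list(self.reference_nrpm)

    def to_json(self, path) -> None:
        payload = {
            "hk_genes": self.hk_genes,
            "hk_rpm_profile": self.hk_rpm_profile,
            "reference_nrpm": {g: v.tolist() for g, v in self.reference_nrpm.items()},
            "reference_size": self.reference_size,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "ReferenceModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            hk_genes=payload["hk_genes"],
            hk_rpm_profile={k: float(v) for k, v in payload["hk_rpm_profile"].items()},
            reference_nrpm={k: np.asarray(v, dtype=float) for k, v in payload["reference_nrpm"].items()},
            reference_size=int(payload["reference_size"]),
        )


@dataclass
class PercentileProfile:
    """Per-sample nRPM values, percentile ranks, and categories."""

    sample_id: str
    nrpm: dict[str, float]
    rank: dict[str, float]
    category: dict[str, str]


def subtract_background(sample_counts: np.ndarray, ntc_counts: np.ndarray) -> np.ndarray:
    """Subtract NTC counts gene-wise, flooring at zero."""
    sample_counts = np.asarray(sample_counts)
    ntc_counts = np.asarray(ntc_counts)
    if sample_counts.shape != ntc_counts.shape:
        raise ValueError("sample and NTC vectors must have equal length")
    if np.any(sample_counts < 0) or np.any(ntc_counts < 0):
        raise ValueError("counts must be non-negative")
    return np.maximum(sample_counts - ntc_counts, 0)


def to_rpm(adjusted: np.ndarray) -> np.ndarray:
    """Scale background-subtracted counts to reads per million."""
    adjusted = np.asarray(adjusted, dtype=float)
    total = adjusted.sum()
    if total <= 0:
        raise ZeroDepthError("sample has zero background-subtracted reads")
    return adjusted * 1e6 / total


def normalization_ratio(
    sample_hk_rpm: Mapping[str, float], hk_rpm_profile: Mapping[str, float]
) -> float:
    """Median of per-housekeeping-gene RPM ratios against the locked profile.

    The median of an even number of ratios is the mean of the two central
    values.  A single dropped-out housekeeping gene does not move the
    ratio; a sample with *no* housekeeping signal is a QC failure.
    """
    ratios = []
    for g, profile_val in hk_rpm_profile.items():
        if profile_val > 0:
            ratios.append(sample_hk_rpm[g] / profile_val)
    if not ratios:
        raise ValueError("no housekeeping gene with a positive profile value")
    if all(r == 0 for r in ratios):
        raise ZeroDepthError("all housekeeping RPMs are zero (QC fail)")
    return float(np.median(ratios))


def compute_nrpm(
    sample_counts: np.ndarray,
    ntc_counts: np.ndarray,
    gene_ids: Sequence[str],
    model: ReferenceModel,
    numerator: str = "rpm",
) -> dict[str, float]:
    """Chain background subtraction -> RPM -> Normalization Ratio -> nRPM.

    ``numerator`` selects what is divided by the Normalization Ratio:
    ``"rpm"`` (depth-normalized, the default) or ``"reads"`` (raw
    background-subtracted counts, for sensitivity analysis).
    """
    if numerator not in ("rpm", "reads"):
        raise ValueError(f"unknown numerator {numerator!r}")
    adjusted = subtract_background(sample_counts, ntc_counts)
    rpm = to_rpm(adjusted)
    idx = {g: i for i, g in enumerate(gene_ids)}
    sample_hk = {g: float(rpm[idx[g]]) for g in model.hk_genes}
    ratio = normalization_ratio(sample_hk, model.hk_rpm_profile)
    base = rpm if numerator == "rpm" else adjusted.astype(float)
    return {g: float(base[idx[g]] / ratio) for g in gene_ids}


def percentile_rank(value: float, reference: np.ndarray) -> float:
    """Mid-rank percentile of ``value`` within a sorted reference vector.

    rank = 100 * (#{r < v} + 0.5 * #{r == v}) / N.
    """
    reference = np.asarray(reference)
    if reference.size == 0:
        raise ValueError("empty reference vector")
    lo = np.searchsorted(reference, value, side="left")
    hi = np.searchsorted(reference, value, side="right")
    return 100.0 * (lo + 0.5 * (hi - lo)) / reference.size


def percentile_rank_vector(values: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Vectorized :func:`percentile_rank` over many query values."""
    reference = np.asarray(reference)
    if reference.size == 0:
        raise ValueError("empty reference vector")
    values = np.asarray(values)
    lo = np.searchsorted(reference, values, side="left")
    hi = np.searchsorted(reference, values, side="right")
    return 100.0 * (lo + 0.5 * (hi - lo)) / reference.size


def categorize(rank: float) -> str:
    """Map a percentile rank to low (<25) / moderate (25-<75) / high (>=75)."""
    if not (0.0 <= rank <= 100.0):
        raise ValueError(f"rank {rank} outside [0, 100]")
    if rank >= HIGH_CUTOFF:
        return CATEGORY_HIGH
    if rank >= LOW_CUTOFF:
        return CATEGORY_MODERATE
    return CATEGORY_LOW


def categorize_vector(ranks: np.ndarray) -> np.ndarray:
    ranks = np.asarray(ranks, dtype=float)
    if np.any((ranks < 0) | (ranks > 100)):
        raise ValueError("ranks outside [0, 100]")
    out = np.full(ranks.shape, CATEGORY_MODERATE, dtype=object)
    out[ranks >= HIGH_CUTOFF] = CATEGORY_HIGH
    out[ranks < LOW_CUTOFF] = CATEGORY_LOW
    return out


def _cohort_nrpm(
    raw: RawPanelCounts, hk_genes: Sequence[str], hk_rpm_profile: Mapping[str, float] | None
) -> tuple[np.ndarray, list[str], list[QCFailure], dict[str, float]]:
    """nRPM matrix for every QC-passing sample.

    When ``hk_rpm_profile`` is None it is derived from the cohort itself
    (per-housekeeping-gene median RPM), which is how the locked reference
    profile is first established.
    """
    gene_idx = {g: i for i, g in enumerate(raw.gene_ids)}
    hk_cols = [gene_idx[g] for g in hk_genes]

    rpm_rows, kept, failures = [], [], []
    for i, sid in enumerate(raw.sample_ids):
        adjusted = subtract_background(raw.counts[i], raw.ntc_for(sid))
        total = adjusted.sum()
        if total <= 0:
            failures.append(QCFailure(sid, "zero background-subtracted depth"))
            continue
        rpm_rows.append(adjusted * 1e6 / total)
        kept.append(sid)
    if not rpm_rows:
        raise ZeroDepthError("every sample failed zero-depth QC")
    rpm = np.vstack(rpm_rows)

    if hk_rpm_profile is None:
        profile_vals = np.median(rpm[:, hk_cols], axis=0)
        hk_rpm_profile = dict(zip(hk_genes, profile_vals))

    profile_vec = np.array([hk_rpm_profile[g] for g in hk_genes], dtype=float)
    if np.any(profile_vec <= 0):
        bad = [g for g, v in zip(hk_genes, profile_vec) if v <= 0]
        raise DegenerateReferenceError(f"housekeeping profile non-positive for {bad}")
    ratios = np.median(rpm[:, hk_cols] / profile_vec, axis=1)

    ok = ratios > 0
    for sid, flag in zip(list(kept), ok):
        if not flag:
            failures.append(QCFailure(sid, "zero housekeeping signal"))
    kept = [sid for sid, flag in zip(kept, ok) if flag]
    nrpm = rpm[ok] / ratios[ok, None]
    return nrpm, kept, failures, dict(hk_rpm_profile)


def build_reference_model(raw: RawPanelCounts, hk_genes: Sequence[str]) -> ReferenceModel:
    """Build the locked reference: housekeeping profile + sorted nRPM vectors."""
    missing = [g for g in hk_genes if g not in raw.gene_ids]
    if missing:
        raise ValueError(f"housekeeping genes absent from panel: {missing}")
    nrpm, kept, failures, profile = _cohort_nrpm(raw, hk_genes, None)
    if failures:
        warnings.warn(f"{len(failures)} reference samples failed QC and were excluded")
    reference_nrpm = {}
    for j, g in enumerate(raw.gene_ids):
        col = np.sort(nrpm[:, j])
        if np.unique(col).size < 2:
            raise DegenerateReferenceError(f"gene {g!r} has < 2 distinct reference nRPM values")
        reference_nrpm[g] = col
    return ReferenceModel(
        hk_genes=list(hk_genes),
        hk_rpm_profile={g: float(v) for g, v in profile.items()},
        reference_nrpm=reference_nrpm,
        reference_size=len(kept),
    )


def percentile_table(
    raw: RawPanelCounts, model: ReferenceModel
) -> tuple[pd.DataFrame, list[QCFailure]]:
    """Rank every sample against the reference model.

    Returns a tidy frame with columns ``sample, gene, nrpm, rank, category``
    (QC-passing samples only) plus the list of QC failures.
    """
    nrpm, kept, failures, _ = _cohort_nrpm(raw, model.hk_genes, model.hk_rpm_profile)
    frames = []
    for j, g in enumerate(raw.gene_ids):
        if g not in model.reference_nrpm:
            continue
        ranks = percentile_rank_vector(nrpm[:, j], model.reference_nrpm[g])
        frames.append(
            pd.DataFrame(
                {
                    "sample": kept,
                    "gene": g,
                    "nrpm": nrpm[:, j],
                    "rank": ranks,
                    "category": categorize_vector(ranks),
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    table = table.sort_values(["sample", "gene"], kind="stable").reset_index(drop=True)
    return table, failures
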