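"""Kaplan-Meier estimation, log-rank comparison, and Cox regression.

Three endpoints are analyzed: overall survival from advanced/metastatic
disease in immunotherapy-naive patients, and overall / progression-free
survival from immunotherapy initiation in the treated subset.  The gene of
interest enters either as the binary high category (rank >= 75) or as the
continuous percentile rank (per-unit hazard ratio).

Kaplan-Meier curves and the log-rank test are delegated to lifelines; the
Cox model maximizes the partial likelihood by Newton-Raphson with the Efron
tie correction by default (Breslow available), which also makes the score
test at beta = 0 coincide with the log-rank statistic for a single binary
covariate under Breslow ties.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.utils import median_survival_times
from scipy import stats

__all__ = [
    "KMEstimate",
    "SurvivalFit",
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "cox_loglik",
    "build_survival_cohorts",
]


@dataclass
class KMEstimate:
    times: np.ndarray
    survival: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    median: float           # NaN when the curve never reaches 0.5
    median_ci: tuple[float, float]
    n: int
    n_events: int

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return float(self.survival[idx]) if idx >= 0 else 1.0


def km_estimate(durations: np.ndarray, events: np.ndarray) -> KMEstimate:
    """Product-limit estimate with Greenwood/log-log CIs and median."""
    durations = np.asarray(durations, dtype=float)
    events = np.asarray(events, dtype=int)
    if durations.size == 0:
        raise ValueError("no records")
    kmf = KaplanMeierFitter()
    kmf.fit(durations, events)
    ci = kmf.confidence_interval_survival_function_
    median = kmf.median_survival_time_
    med_ci = median_survival_times(kmf.confidence_interval_)
    lo, hi = float(med_ci.iloc[0, 0]), float(med_ci.iloc[0, 1])
    return KMEstimate(
        times=kmf.survival_function_.index.to_numpy(),
        survival=kmf.survival_function_["KM_estimate"].to_numpy(),
        ci_lower=ci.iloc[:, 0].to_numpy(),
        ci_upper=ci.iloc[:, 1].to_numpy(),
        median=float(median) if np.isfinite(median) else float("nan"),
        median_ci=(lo, hi),
        n=int(durations.size),
        n_events=int(events.sum()),
    )


def logrank_test(
    durations: np.ndarray, events: np.ndarray, group: np.ndarray
) -> tuple[float, float]:
    """Two-group log-rank statistic (1 df chi-square) and p-value."""
    group = np.asarray(group, dtype=bool)
    if group.all() or (~group).all():
        raise ValueError("both strata must be non-empty")
    res = _ll_logrank(
        np.asarray(durations)[group], np.asarray(durations)[~group],
        event_observed_A=np.asarray(events)[group],
        event_observed_B=np.asarray(events)[~group],
    )
    return float(res.test_statistic), float(res.p_value)


def cox_loglik(
    beta: np.ndarray,
    X: np.ndarray,
    durations: np.ndarray,
    events: np.ndarray,
    ties: str = "efron",
) -> tuple[float, np.ndarray, np.ndarray]:
    """Cox partial log-likelihood with gradient and Hessian.

    Vectorized over risk sets via suffix sums after sorting by time; tied
    event times are handled by the Efron or Breslow approximation.
    """
    order = np.argsort(durations, kind="stable")
    X = X[order]
    t = durations[order]
    e = events[order].astype(bool)
    n, k = X.shape

    eta = X @ beta
    eta = eta - eta.max()  # guard overflow; cancels in all ratios
    w = np.exp(eta)
    wx = w[:, None] * X
    wxx = wx[:, :, None] * X[:, None, :]

    # suffix sums: risk set at time t(i) = samples i..n-1 (ties share a set)
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum(wx[::-1], axis=0)[::-1]
    S2 = np.cumsum(wxx[::-1], axis=0)[::-1]

    ll = 0.0
    grad = np.zeros(k)
    hess = np.zeros((k, k))
    i = 0
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        d_idx = np.arange(i, j)[e[i:j]]
        d = d_idx.size
        if d > 0:
            s0, s1, s2 = S0[i], S1[i], S2[i]
            ll += eta[d_idx].sum()
            grad += X[d_idx].sum(axis=0)
            if ties == "breslow":
                ll -= d * np.log(s0)
                grad -= d * s1 / s0
                hess -= d * (s2 / s0 - np.outer(s1, s1) / s0**2)
            elif ties == "efron":
                t0 = w[d_idx].sum()
                t1 = wx[d_idx].sum(axis=0)
                t2 = wxx[d_idx].sum(axis=0)
                for l in range(d):
                    f = l / d
                    z0 = s0 - f * t0
                    z1 = s1 - f * t1
                    z2 = s2 - f * t2
                    ll -= np.log(z0)
                    grad -= z1 / z0
                    hess -= z2 / z0 - np.outer(z1, z1) / z0**2
            else:
                raise ValueError(f"unknown ties method {ties!r}")
        i = j
    return float(ll), grad, hess


@dataclass
class SurvivalFit:
    model: str
    coefficients: pd.DataFrame  # covariate, coef, se, hr, hr_lo, hr_hi, p
    log_likelihood: float
    n: int
    n_events: int
    ties: str
    converged: bool
    n_iterations: int
    separation_flag: bool = False


def cox_fit(
    data: pd.DataFrame,
    duration_col: str,
    event_col: str,
    covariates: list[str],
    ties: str = "efron",
    tol: float = 1e-9,
    max_iter: int = 50,
) -> SurvivalFit:
    """Newton-Raphson Cox proportional-hazards fit with Wald inference."""
    sub = data[[duration_col, event_col, *covariates]].dropna()
    X = sub[covariates].to_numpy(dtype=float)
    durations = sub[duration_col].to_numpy(dtype=float)
    events = sub[event_col].to_numpy(dtype=float)
    if events.sum() < 1:
        raise ValueError("at least one event is required")
    if np.linalg.matrix_rank(X - X.mean(axis=0)) < X.shape[1]:
        raise ValueError("design matrix is not full rank")
    # center and scale covariates for conditioning (beta is rescaled back)
    center = X.mean(axis=0)
    sds = X.std(axis=0)
    sds[sds == 0] = 1.0
    Xc = (X - center) / sds

    beta = np.zeros(X.shape[1])
    converged = False
    separation = False
    trace = []
    for it in range(1, max_iter + 1):
        ll, grad, hess = cox_loglik(beta, Xc, durations, events, ties)
        trace.append(ll)
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError(f"singular information matrix at iteration {it}") from exc
        if not np.all(np.isfinite(step)):
            separation = True  # monotone likelihood: information degenerates
            break
        # step-halving if the likelihood would decrease
        alpha = 1.0
        for _ in range(30):
            ll_new, *_ = cox_loglik(beta + alpha * step, Xc, durations, events, ties)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            alpha *= 0.5
        beta = beta + alpha * step
        if np.max(np.abs(beta)) > 20:
            separation = True
            break
        if np.max(np.abs(alpha * step)) < tol:
            converged = True
            break
    if not converged and not separation:
        raise RuntimeError(
            f"Cox Newton-Raphson failed to converge in {max_iter} iterations; "
            f"log-likelihood trace: {[round(v, 4) for v in trace]}"
        )

    ll, grad, hess = cox_loglik(beta, Xc, durations, events, ties)
    cov = np.linalg.inv(-hess)
    beta = beta / sds
    cov = cov / np.outer(sds, sds)
    se = np.sqrt(np.diag(cov))
    zcrit = 1.959963984540054
    p = 2.0 * stats.norm.sf(np.abs(beta) / se)
    coef = pd.DataFrame(
        {
            "covariate": covariates,
            "coef": beta,
            "se": se,
            "hr": np.exp(beta),
            "hr_lo": np.exp(beta - zcrit * se),
            "hr_hi": np.exp(beta + zcrit * se),
            "p": p,
        }
    )
    return SurvivalFit(
        model="cox",
        coefficients=coef,
        log_likelihood=ll,
        n=len(sub),
        n_events=int(events.sum()),
        ties=ties,
        converged=converged,
        n_iterations=len(trace),
        separation_flag=separation,
    )


def build_survival_cohorts(
    clinical: pd.DataFrame,
) -> tuple[dict[str, pd.DataFrame], list[str]]:
    """Split the clinical table into the three endpoint cohorts.

    Returns ``{"os_naive", "os_ici", "pfs_ici"}`` plus the sample ids
    rejected for non-positive or missing durations.
    """
    curated = clinical[clinical["has_clinical"].astype(bool)]
    rejected: list[str] = []

    def _records(sub: pd.DataFrame, tcol: str, ecol: str) -> pd.DataFrame:
        out = sub[["sample", tcol, ecol]].rename(
            columns={tcol: "time_months", ecol: "event"}
        )
        bad = out["time_months"].isna() | (out["time_months"] <= 0) | out["event"].isna()
        rejected.extend(out.loc[bad, "sample"].tolist())
        out = out[~bad].copy()
        out["event"] = out["event"].astype(int)
        return out.reset_index(drop=True)

    naive = curated[~curated["ici_treated"].astype(bool)]
    ici = curated[curated["ici_treated"].astype(bool)]
    cohorts = {
        "os_naive": _records(naive, "os_advanced_months", "os_advanced_event"),
        "os_ici": _records(ici, "os_ici_months", "os_ici_event"),
        "pfs_ici": _records(ici, "pfs_ici_months", "pfs_ici_event"),
    }
    return cohorts, rejected
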