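"""Cohort-level association statistics for a gene-of-interest's high group.

Covers the per-cancer-type landscape of low/moderate/high categories, the
receptor-high / ligand-low-moderate agonist-candidate profile, the
univariable odds-ratio screen, multivariable logistic regression pooled over
multiply imputed datasets (chained equations + Rubin's rules), Spearman
correlation, and 2x2 cross-tabulations with Fisher's exact test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .normalize import CATEGORY_HIGH, HIGH_CUTOFF

__all__ = [
    "AssociationResult",
    "CrosstabResult",
    "binarize_high",
    "landscape_by_type",
    "agonist_candidate_profile",
    "univariable_or",
    "univariable_screen",
    "multivariable_logistic_mi",
    "spearman",
    "crosstab_signature",
    "combined_signature",
]


@dataclass
class AssociationResult:
    """One odds-ratio row: variable, contrasted level, OR with Wald CI/p."""

    variable: str
    condition: str
    odds_ratio: float
    ci95: tuple[float, float]
    p_value: float
    stage: str = "univariable"
    counts: tuple[int, int, int, int] | None = None
    corrected: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if not (lo <= self.odds_ratio <= hi):
            raise ValueError("odds ratio must lie inside its CI")


def binarize_high(table: pd.DataFrame, gene: str) -> pd.Series:
    """Indicator of the high category (rank >= 75) for a tracked gene."""
    col = f"category_{gene}"
    if col not in table.columns:
        raise KeyError(f"gene {gene!r} is not tracked in the cohort table")
    return (table[col] == CATEGORY_HIGH).astype(int)


def landscape_by_type(
    table: pd.DataFrame, gene: str, min_samples: int = 11
) -> pd.DataFrame:
    """Per-cancer-type low/moderate/high fractions plus an All-Cancers row.

    Only types with at least ``min_samples`` samples get their own row.
    """
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    if table.empty:
        raise ValueError("empty cohort table")
    col = f"category_{gene}"

    def _fracs(sub: pd.DataFrame) -> dict[str, float]:
        n = len(sub)
        counts = sub[col].value_counts()
        return {
            "n": n,
            "frac_low": counts.get("low", 0) / n,
            "frac_moderate": counts.get("moderate", 0) / n,
            "frac_high": counts.get("high", 0) / n,
        }

    rows = [{"cancer_type": "All Cancers", **_fracs(table)}]
    for ctype, sub in table.groupby("cancer_type"):
        if len(sub) >= min_samples:
            rows.append({"cancer_type": ctype, **_fracs(sub)})
    return pd.DataFrame(rows)


def agonist_candidate_profile(
    table: pd.DataFrame,
    receptor: str = "CD40",
    ligand: str = "CD40LG",
    min_samples: int = 20,
) -> pd.DataFrame:
    """Per-type fraction of receptor-high AND ligand-low/moderate samples.

    The biologically attractive agonist profile: the receptor transcript in
    the top quartile while its ligand stays below the 75th percentile.
    """
    if receptor == ligand:
        raise ValueError("receptor and ligand must differ")
    flagged = (table[f"category_{receptor}"] == CATEGORY_HIGH) & (
        table[f"rank_{ligand}"] < HIGH_CUTOFF
    )
    rows = [
        {
            "cancer_type": "All Cancers",
            "n": len(table),
            "n_flagged": int(flagged.sum()),
            "frac_flagged": flagged.mean(),
        }
    ]
    for ctype, idx in table.groupby("cancer_type").groups.items():
        if len(idx) >= min_samples:
            sub = flagged.loc[idx]
            rows.append(
                {
                    "cancer_type": ctype,
                    "n": len(idx),
                    "n_flagged": int(sub.sum()),
                    "frac_flagged": sub.mean(),
                }
            )
    return pd.DataFrame(rows)


def univariable_or(
    a: int, b: int, c: int, d: int, variable: str = "", condition: str = ""
) -> AssociationResult:
    """Cross-product odds ratio with Wald CI and two-sided p.

    Layout: rows = variable yes/no, columns = outcome yes/no, so
    OR = (a*d)/(b*c).  Any zero cell triggers the Haldane-Anscombe +0.5
    correction (flagged on the result).
    """
    cells = [a, b, c, d]
    if any(x < 0 for x in cells):
        raise ValueError("counts must be non-negative")
    if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
        raise ValueError("both margins must be positive")
    corrected = any(x == 0 for x in cells)
    if corrected:
        cells = [x + 0.5 for x in cells]
    a_, b_, c_, d_ = cells
    or_ = (a_ * d_) / (b_ * c_)
    se = math.sqrt(1 / a_ + 1 / b_ + 1 / c_ + 1 / d_)
    lo, hi = or_ * math.exp(-1.959963984540054 * se), or_ * math.exp(1.959963984540054 * se)
    z = abs(math.log(or_)) / se
    p = 2.0 * stats.norm.sf(z)
    return AssociationResult(
        variable=variable,
        condition=condition,
        odds_ratio=or_,
        ci95=(lo, hi),
        p_value=float(max(p, np.finfo(float).tiny)),
        stage="univariable",
        counts=(a, b, c, d),
        corrected=corrected,
    )


def _counts_2x2(exposure: pd.Series, outcome: pd.Series) -> tuple[int, int, int, int]:
    exposure = exposure.astype(bool)
    outcome = outcome.astype(bool)
    a = int((exposure & outcome).sum())
    b = int((exposure & ~outcome).sum())
    c = int((~exposure & outcome).sum())
    d = int((~exposure & ~outcome).sum())
    return a, b, c, d


def candidate_cancer_types(
    table: pd.DataFrame, outcome: pd.Series, min_samples: int = 15
) -> list[str]:
    """Cancer types eligible for the screen: n >= min_samples OR a
    high-outcome fraction above the cohort average."""
    avg = outcome.mean()
    eligible = []
    for ctype, idx in table.groupby("cancer_type").groups.items():
        if len(idx) >= min_samples or outcome.loc[idx].mean() > avg:
            eligible.append(ctype)
    return sorted(eligible)


def univariable_screen(
    table: pd.DataFrame,
    outcome_gene: str,
    immune_genes: list[str],
    alpha: float = 0.05,
    min_type_samples: int = 15,
) -> tuple[list[AssociationResult], list[str]]:
    """One univariable odds ratio per candidate; p <= alpha enters the
    multivariable model.

    Candidates: age >= 61, male sex, each eligible cancer type, MSI
    unstable, TMB >= 10/Mb, PD-L1 IHC positive, and the high category of
    every other tracked immune gene.  MSI/TMB use complete cases at this
    stage.  Constant candidates are skipped with a warning.
    """
    outcome = binarize_high(table, outcome_gene)
    candidates: list[tuple[str, str, pd.Series, pd.Series]] = []

    candidates.append(("age", ">=61", table["age_years"] >= 61, outcome))
    candidates.append(("sex", "male", table["sex"] == "male", outcome))
    for ctype in candidate_cancer_types(table, outcome, min_type_samples):
        candidates.append((f"cancer_type:{ctype}", "yes", table["cancer_type"] == ctype, outcome))
    if "msi" in table.columns:
        obs = table["msi"].notna()
        candidates.append(("msi", "unstable", table.loc[obs, "msi"] == "unstable", outcome[obs]))
    if "tmb_high" in table.columns:
        obs = table["tmb_high"].notna()
        candidates.append(
            ("tmb", ">=10/Mb", table.loc[obs, "tmb_high"].astype(str) == "true", outcome[obs])
        )
    if "pdl1_positive" in table.columns:
        candidates.append(
            ("pdl1_ihc", "positive", table["pdl1_positive"].astype(str) == "true", outcome)
        )
    for gene in immune_genes:
        if gene == outcome_gene:
            continue
        candidates.append((f"rna:{gene}", "high", binarize_high(table, gene).astype(bool), outcome))

    results, selected = [], []
    for name, condition, exposure, out in candidates:
        if exposure.nunique() < 2:
            warnings.warn(f"candidate {name!r} is constant; skipped")
            continue
        a, b, c, d = _counts_2x2(exposure, out)
        res = univariable_or(a, b, c, d, variable=name, condition=condition)
        results.append(res)
        if res.p_value <= alpha:
            selected.append(name)
    return results, selected


def _fit_logistic(X: np.ndarray, y: np.ndarray, ridge: float = 0.0):
    """Logistic MLE via statsmodels; ridge-stabilized IRLS fallback on
    separation/non-convergence.  Returns (beta, cov, flagged)."""
    if ridge == 0.0:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
            if np.all(np.isfinite(fit.params)) and np.all(np.isfinite(np.diag(fit.cov_params()))):
                beta = np.asarray(fit.params, dtype=float)
                if np.max(np.abs(beta)) < 15:
                    return beta, np.asarray(fit.cov_params(), dtype=float), False
        except Exception:
            pass
        ridge = 1e-3
    # ridge-penalized IRLS
    beta = np.zeros(X.shape[1])
    for _ in range(100):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1 - mu)
        H = X.T @ (X * w[:, None]) + ridge * np.eye(X.shape[1])
        g = X.T @ (y - mu) - ridge * beta
        step = np.linalg.solve(H, g)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1 - mu)
    H = X.T @ (X * w[:, None]) + ridge * np.eye(X.shape[1])
    return beta, np.linalg.inv(H), True


def _check_collinearity(design: pd.DataFrame) -> None:
    cols = design.columns
    arr = design.to_numpy(dtype=float)
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            if np.array_equal(arr[:, i], arr[:, j]):
                raise ValueError(f"collinear covariates: {cols[i]!r} and {cols[j]!r} are identical")
    if np.linalg.matrix_rank(arr) < arr.shape[1]:
        raise ValueError("design matrix is rank deficient")


def multivariable_logistic_mi(
    design: pd.DataFrame,
    outcome: pd.Series,
    m: int = 20,
    burn_in: int = 10,
    seed: int = 0,
) -> list[AssociationResult]:
    """Multivariable logistic regression pooled over ``m`` imputations.

    ``design`` holds numeric 0/1 (or continuous) covariates with NaN only in
    the columns that carry missing values (MSI/TMB).  Missing binaries are
    imputed by chained logistic models (given all other covariates plus the
    outcome) with posterior-draw parameters; completed datasets are fitted
    by maximum likelihood and pooled by Rubin's rules with Barnard-Rubin
    degrees of freedom.  With no missing data the pooled fit collapses to
    the single complete-data fit (between-imputation variance 0).
    """
    if m < 2:
        raise ValueError("at least 2 imputations are required")
    design = design.astype(float)
    y = outcome.to_numpy(dtype=float)
    _check_collinearity(design.fillna(design.mean()))
    rng = np.random.default_rng(seed)

    miss_cols = [c for c in design.columns if design[c].isna().any()]
    names = list(design.columns)
    k = len(names) + 1  # + intercept
    n = len(design)

    params = np.empty((m, k))
    variances = np.empty((m, k))
    any_flagged = False
    for j in range(m):
        data = design.copy()
        # initial fill: draws from each column's observed marginal
        for c in miss_cols:
            obs = data[c].dropna().to_numpy()
            data.loc[data[c].isna(), c] = rng.choice(obs, size=data[c].isna().sum())
        cycles = burn_in if miss_cols else 0
        for _ in range(cycles):
            for c in miss_cols:
                others = [cc for cc in names if cc != c]
                X_full = np.column_stack(
                    [np.ones(n), data[others].to_numpy(dtype=float), y]
                )
                observed = design[c].notna().to_numpy()
                beta, cov, _ = _fit_logistic(
                    X_full[observed], design.loc[observed, c].to_numpy(dtype=float)
                )
                try:
                    chol = np.linalg.cholesky(cov)
                    beta_draw = beta + chol @ rng.standard_normal(len(beta))
                except np.linalg.LinAlgError:
                    beta_draw = beta
                p_miss = 1.0 / (1.0 + np.exp(-(X_full[~observed] @ beta_draw)))
                data.loc[~observed, c] = (rng.random(p_miss.shape) < p_miss).astype(float)
        X = np.column_stack([np.ones(n), data.to_numpy(dtype=float)])
        beta, cov, flagged = _fit_logistic(X, y)
        any_flagged = any_flagged or flagged
        params[j] = beta
        variances[j] = np.diag(cov)

    qbar = params.mean(axis=0)
    W = variances.mean(axis=0)
    B = params.var(axis=0, ddof=1)
    T = W + (1 + 1 / m) * B

    # Barnard-Rubin small-sample degrees of freedom
    nu_com = n - k
    lam = np.clip((1 + 1 / m) * B / T, 1e-12, 1 - 1e-12)
    nu_old = (m - 1) / lam**2
    nu_obs = (nu_com + 1) / (nu_com + 3) * nu_com * (1 - lam)
    df = 1.0 / (1.0 / nu_old + 1.0 / nu_obs)

    results = []
    tcrit = stats.t.ppf(0.975, df)
    se = np.sqrt(T)
    pvals = 2.0 * stats.t.sf(np.abs(qbar) / se, df)
    for i, name in enumerate(["(intercept)", *names]):
        results.append(
            AssociationResult(
                variable=name,
                condition="",
                odds_ratio=float(np.exp(qbar[i])),
                ci95=(
                    float(np.exp(qbar[i] - tcrit[i] * se[i])),
                    float(np.exp(qbar[i] + tcrit[i] * se[i])),
                ),
                p_value=float(max(pvals[i], np.finfo(float).tiny)),
                stage="multivariable",
                corrected=any_flagged,
            )
        )
    return results


def spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Tie-aware Spearman rho with the t-approximation p (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("Spearman rho undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def combined_signature(table: pd.DataFrame, genes: tuple[str, str] = ("CD4", "CD8A"), rule: str = "any") -> pd.Series:
    """High CD4/CD8 signature: high if any (default) or all members are high."""
    flags = pd.concat([binarize_high(table, g).astype(bool) for g in genes], axis=1)
    if rule == "any":
        return flags.any(axis=1)
    if rule == "all":
        return flags.all(axis=1)
    raise ValueError(f"unknown rule {rule!r}")


@dataclass
class CrosstabResult:
    counts: tuple[int, int, int, int]  # (a, b, c, d): rows = group yes/no
    row_percent: tuple[int, int]       # a/(a+b), c/(c+d) as nearest percents
    p_value: float


def crosstab_signature(group_a: pd.Series, group_b: pd.Series) -> CrosstabResult:
    """2x2 of two indicators with row percentages and Fisher's exact p."""
    a, b, c, d = _counts_2x2(group_a, group_b)
    if (a + b) == 0 or (c + d) == 0:
        raise ValueError("empty row margin")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return CrosstabResult(
        counts=(a, b, c, d),
        row_percent=(round(100 * a / (a + b)), round(100 * c / (c + d))),
        p_value=float(p),
    )
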