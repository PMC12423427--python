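"""Severity stratification and the cross-sectional statistical battery.

Group comparisons (pooled-variance t and Yates-corrected chi-square),
standardized-beta OLS with named covariate sets, per-stratum
Benjamini-Hochberg FDR, Pearson association, and the across-network
one-way repeated-measures ANOVA with Greenhouse-Geisser correction and
Tukey-style post hoc pairwise comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

#: Named covariate sets for each analysis track.  ``baseline_score`` in the
#: longitudinal set is a placeholder replaced by the concrete baseline column
#: of the outcome being modeled.
_COVARIATE_SETS: dict[str, tuple[str, ...]] = {
    # mild-vs-severe comparison of network coupling (group is the predictor)
    "group_compare": ("age", "sex"),
    # WMH volume -> network coupling
    "wmh_coupling": ("age", "sex"),
    # same, additionally adjusted for education and vascular risk factors
    "wmh_coupling_full": (
        "age",
        "sex",
        "education",
        "hypertension",
        "diabetes",
        "hypercholesterolemia",
        "smoking",
        "drinking",
    ),
    # coupling -> baseline cognition
    "coupling_cognition": ("age", "sex", "education", "wmh_volume"),
    # coupling -> follow-up cognition
    "longitudinal": (
        "age",
        "sex",
        "education",
        "wmh_volume",
        "follow_up_duration",
        "baseline_score",
    ),
}


@dataclass
class AssociationResult:
    """One fitted model: standardized beta for the predictor of interest,
    raw and FDR-adjusted p, and the complete-case n."""

    stratum: str
    outcome: str
    predictor: str
    covariates: tuple[str, ...]
    beta_std: float
    p_raw: float
    n: int
    p_fdr: float = float("nan")
    ci_low: float = float("nan")
    ci_high: float = float("nan")


@dataclass
class AnovaResult:
    """Greenhouse-Geisser corrected one-way repeated-measures ANOVA.

    ``df1 = epsilon * (k - 1)`` and ``df2 = epsilon * (k - 1) * (N - 1)``;
    ``posthoc`` holds all-pairs paired comparisons as t values with
    Tukey-adjusted p (studentized-range distribution on the pooled
    within-subject error).
    """

    F: float
    df1: float
    df2: float
    epsilon: float
    p: float
    posthoc: pd.DataFrame = field(default_factory=pd.DataFrame)


def classify_severity(pwmh: int, dwmh: int) -> str:
    """WMH severity from periventricular and deep Fazekas scores.

    Severe iff PWMH = 3 or DWMH >= 2, otherwise mild.  Both scores zero is
    an inclusion error (the cohort requires Fazekas > 0).
    """
    pwmh, dwmh = int(pwmh), int(dwmh)
    if not (0 <= pwmh <= 3 and 0 <= dwmh <= 3):
        raise ValueError(f"Fazekas scores must be in 0..3, got ({pwmh}, {dwmh})")
    if pwmh == 0 and dwmh == 0:
        raise ValueError("PWMH + DWMH must be > 0 for inclusion")
    return "severe" if (pwmh == 3 or dwmh >= 2) else "mild"


def add_severity(table: pd.DataFrame) -> pd.DataFrame:
    """Vectorized severity column from ``pwmh``/``dwmh`` columns."""
    out = table.copy()
    out["severity"] = [
        classify_severity(p, d) for p, d in zip(out["pwmh"], out["dwmh"])
    ]
    return out


def zscore_battery(table: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """Standardize test columns to mean 0, SD 1 (n-1 denominator).

    Missing values are ignored in the moments and preserved in the output.
    """
    out = table.copy()
    for col in columns:
        x = out[col].astype(float)
        obs = x.dropna()
        if obs.nunique() < 2:
            raise ValueError(f"test {col!r} is constant; z-score undefined")
        out[col] = (x - obs.mean()) / obs.std(ddof=1)
    return out


def compare_groups(
    table: pd.DataFrame,
    variables: list[str],
    group_col: str = "severity",
    continuity: bool = True,
) -> pd.DataFrame:
    """Mild-vs-severe comparison of baseline characteristics.

    Continuous variables: pooled-variance two-sample t-test.  Binary
    variables (two distinct values): chi-square on the 2x2 table, with Yates
    continuity correction by default.
    """
    groups = sorted(table[group_col].dropna().unique())
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 strata in {group_col!r}, got {groups}")
    g1 = table[table[group_col] == groups[0]]
    g2 = table[table[group_col] == groups[1]]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each stratum needs at least 2 subjects")
    rows = []
    for var in variables:
        x1 = g1[var].dropna()
        x2 = g2[var].dropna()
        values = pd.concat([x1, x2]).unique()
        if len(values) == 2:
            lev = sorted(values.tolist())
            tab = np.array(
                [
                    [(x1 == lev[1]).sum(), (x1 == lev[0]).sum()],
                    [(x2 == lev[1]).sum(), (x2 == lev[0]).sum()],
                ]
            )
            chi2, p, _, _ = stats.chi2_contingency(tab, correction=continuity)
            rows.append({"variable": var, "test": "chi2", "statistic": chi2, "p": p})
        else:
            t, p = stats.ttest_ind(x1.astype(float), x2.astype(float), equal_var=True)
            rows.append({"variable": var, "test": "t", "statistic": t, "p": p})
    return pd.DataFrame(rows)


def covariate_sets(analysis: str) -> list[str]:
    """Ordered covariate list for a named analysis track."""
    try:
        return list(_COVARIATE_SETS[analysis])
    except KeyError:
        raise ValueError(
            f"unknown analysis {analysis!r}; choose from {sorted(_COVARIATE_SETS)}"
        ) from None


def _design_column(series: pd.Series, name: str) -> pd.Series:
    """Numeric design column; two-level categoricals become 0/1 codes."""
    if series.dtype == object or series.dtype.name == "category" or series.dtype == bool:
        levels = sorted(series.dropna().unique().tolist())
        if len(levels) > 2:
            raise ValueError(
                f"column {name!r} has {len(levels)} levels; only binary "
                "categoricals are coded automatically"
            )
        return series.map({lev: k for k, lev in enumerate(levels)}).astype(float)
    return series.astype(float)


def linear_assoc(
    table: pd.DataFrame,
    outcome: str,
    predictor: str,
    covariates: list[str] | None = None,
    stratum: str = "all",
) -> AssociationResult:
    """OLS association of ``outcome`` with ``predictor`` given covariates.

    Fit on complete cases; the reported coefficient is the conventional
    standardized beta ``b * sd(predictor) / sd(outcome)`` (applied uniformly,
    binary predictors included), with a two-sided p and a 95% CI rescaled the
    same way.
    """
    covariates = list(covariates or [])
    cols = [outcome, predictor, *covariates]
    data = table[cols].copy()
    for c in cols:
        data[c] = _design_column(data[c], c)
    data = data.dropna()
    n = len(data)
    if n < len(covariates) + 3:
        raise ValueError(
            f"only {n} complete cases for {len(covariates)} covariates"
        )
    y = data[outcome].to_numpy(dtype=float)
    X = data[[predictor, *covariates]].to_numpy(dtype=float)
    Xc = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(Xc)
    if rank < Xc.shape[1]:
        _, R = np.linalg.qr(Xc)
        diag = np.abs(np.diag(R))
        aliased = [
            ([ "const", predictor, *covariates])[k]
            for k in np.flatnonzero(diag < 1e-8 * diag.max())
        ]
        raise ValueError(f"rank-deficient design; aliased columns: {aliased}")
    fit = sm.OLS(y, Xc).fit()
    scale = data[predictor].std(ddof=1) / data[outcome].std(ddof=1)
    beta_std = float(fit.params[1] * scale)
    ci = fit.conf_int(alpha=0.05)[1]
    return AssociationResult(
        stratum=stratum,
        outcome=outcome,
        predictor=predictor,
        covariates=tuple(covariates),
        beta_std=beta_std,
        p_raw=float(fit.pvalues[1]),
        n=n,
        ci_low=float(ci[0] * scale),
        ci_high=float(ci[1] * scale),
    )


def fdr_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value family")
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def apply_fdr(results: list[AssociationResult]) -> list[AssociationResult]:
    """Adjust p-values within each stratum family (one family per stratum
    per analysis table), writing ``p_fdr`` in place."""
    by_stratum: dict[str, list[AssociationResult]] = {}
    for r in results:
        by_stratum.setdefault(r.stratum, []).append(r)
    for family in by_stratum.values():
        adj = fdr_bh([r.p_raw for r in family])
        for r, q in zip(family, adj):
            r.p_fdr = float(q)
    return results


def pearson_assoc(x, y) -> tuple[float, float]:
    """Pearson r with two-sided p from the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input; correlation undefined")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def rm_anova_networks(coupling: pd.DataFrame | np.ndarray) -> AnovaResult:
    """One-way within-subject ANOVA across the k network conditions.

    ``coupling`` is subjects x networks (wide); missing cells are an error —
    no imputation.  The Greenhouse-Geisser epsilon (from the double-centered
    condition covariance) is applied to both numerator and denominator df.
    Post hoc all-pairs comparisons use t = (mean_i - mean_j) / sqrt(2 MSe/N)
    on the pooled within-subject error, with Tukey HSD p-values from the
    studentized-range distribution.
    """
    if isinstance(coupling, pd.DataFrame):
        labels = list(coupling.columns)
        Y = coupling.to_numpy(dtype=float)
    else:
        Y = np.asarray(coupling, dtype=float)
        labels = [f"c{k + 1}" for k in range(Y.shape[1])]
    if Y.ndim != 2:
        raise ValueError("coupling must be a 2-D subjects x networks array")
    N, k = Y.shape
    if k < 2 or N < 3:
        raise ValueError(f"need k >= 2 conditions and N >= 3 subjects, got {Y.shape}")
    if not np.isfinite(Y).all():
        raise ValueError("missing or non-finite cells; complete cases required")

    grand = Y.mean()
    col_means = Y.mean(axis=0)
    row_means = Y.mean(axis=1)
    ss_cond = N * float(((col_means - grand) ** 2).sum())
    resid = Y - row_means[:, None] - col_means[None, :] + grand
    ss_err = float((resid**2).sum())
    ss_tot = float(((Y - grand) ** 2).sum())
    df1_u, df2_u = k - 1, (k - 1) * (N - 1)
    ms_cond = ss_cond / df1_u
    ms_err = ss_err / df2_u
    # a condition effect indistinguishable from rounding noise is no effect
    if ss_cond <= 1e-12 * max(ss_tot, 1e-300) or ms_err <= 0:
        F = 0.0
    else:
        F = ms_cond / ms_err

    S = np.cov(Y, rowvar=False)
    Sc = S - S.mean(axis=0)[None, :] - S.mean(axis=1)[:, None] + S.mean()
    denom = (k - 1) * float((Sc**2).sum())
    eps = float(np.trace(Sc) ** 2 / denom) if denom > 0 else 1.0
    eps = float(np.clip(eps, 1.0 / (k - 1), 1.0))
    df1, df2 = eps * df1_u, eps * df2_u
    p = float(stats.f.sf(F, df1, df2)) if F > 0 else 1.0

    rows = []
    se = np.sqrt(2.0 * ms_err / N) if ms_err > 0 else 0.0
    for i in range(k):
        for j in range(i + 1, k):
            diff = col_means[i] - col_means[j]
            t = diff / se if se > 0 else 0.0
            q = abs(t) * np.sqrt(2.0)
            p_adj = float(stats.studentized_range.sf(q, k, df2_u)) if se > 0 else 1.0
            rows.append(
                {
                    "network_a": labels[i],
                    "network_b": labels[j],
                    "mean_diff": diff,
                    "t": t,
                    "p_adj": min(p_adj, 1.0),
                }
            )
    return AnovaResult(
        F=float(F), df1=float(df1), df2=float(df2), epsilon=eps, p=p,
        posthoc=pd.DataFrame(rows),
    )
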