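"""Longitudinal association and quartile-discrimination ROC prognosis.

The prognostic question: does baseline network coupling separate subjects
whose follow-up cognitive score lands in the upper quartile from those in
the lower quartile?  AUC uses the rank (Mann-Whitney) formulation with tie
correction and is *not* forced above 0.5 — the direction follows the
hypothesis that higher coupling predicts upper-quartile performance.  The
95% CI uses the DeLong asymptotic method (bootstrap available).  The
operating cutoff maximizes the Youden index among points whose sensitivity
meets a configurable floor (default 0.90), a sensitivity-prioritized rule
suited to screening for subjects at risk of decline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_stats import AssociationResult, covariate_sets, linear_assoc


@dataclass
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    cutoff: float
    sensitivity: float
    specificity: float
    n_pos: int
    n_neg: int
    curve: pd.DataFrame | None = None  # cutoff, sensitivity, specificity


def longitudinal_assoc(
    table: pd.DataFrame,
    outcome_followup: str,
    predictor_baseline: str,
    baseline_outcome: str,
    stratum: str = "all",
) -> AssociationResult:
    """Follow-up outcome regressed on a baseline predictor with the
    longitudinal covariate set (age, sex, education, baseline WMH volume,
    follow-up duration, and the baseline score of the same test)."""
    covs = covariate_sets("longitudinal")
    covs[covs.index("baseline_score")] = baseline_outcome
    missing = [c for c in (outcome_followup, *covs) if c not in table.columns]
    if missing:
        raise ValueError(f"missing longitudinal columns: {missing}")
    data = table.dropna(subset=[outcome_followup])
    if data.empty:
        raise ValueError("no subjects with follow-up data")
    return linear_assoc(data, outcome_followup, predictor_baseline, covs, stratum)


def quartile_labels(scores) -> np.ndarray:
    """Label follow-up scores as ``upper`` (>= Q3), ``lower`` (<= Q1) or
    ``excluded`` (middle half).

    Quartiles use the inclusive linear-interpolation definition; values tied
    exactly at a boundary all go to the extreme group.
    """
    x = np.asarray(scores, dtype=float)
    if x.ndim != 1 or x.size < 8:
        raise ValueError("need a 1-D vector of at least 8 scores")
    if not np.isfinite(x).all():
        raise ValueError("scores must be finite")
    q1, q3 = np.quantile(x, [0.25, 0.75])
    if q1 == q3:
        raise ValueError("degenerate quartiles: scores are (nearly) constant")
    labels = np.full(x.shape, "excluded", dtype=object)
    labels[x <= q1] = "lower"
    labels[x >= q3] = "upper"
    return labels


def _delong_variance(pos: np.ndarray, neg: np.ndarray) -> float:
    """DeLong variance of the AUC via placement values (structural
    components), with midrank handling of ties."""
    m, n = pos.size, neg.size
    # V10[i] = P(neg < pos_i) + 0.5 P(neg == pos_i), and symmetrically V01
    v10 = np.empty(m)
    for i, p in enumerate(pos):
        v10[i] = ((neg < p).sum() + 0.5 * (neg == p).sum()) / n
    v01 = np.empty(n)
    for j, q in enumerate(neg):
        v01[j] = ((q < pos).sum() + 0.5 * (q == pos).sum()) / m
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def roc_analysis(
    predictor,
    labels,
    positive: str = "upper",
    sens_floor: float = 0.90,
    ci_method: str = "delong",
    n_boot: int = 2000,
    seed: int | None = None,
) -> RocResult:
    """ROC discrimination of the positive class by a continuous predictor.

    ``labels`` may be booleans or the strings produced by
    :func:`quartile_labels` (``excluded`` rows are dropped).  Prediction
    convention: predictor >= cutoff predicts the positive class.
    """
    pred = np.asarray(predictor, dtype=float)
    lab = np.asarray(labels)
    if lab.dtype != bool:
        keep = lab != "excluded"
        pred, lab = pred[keep], lab[keep]
        lab = lab == positive
    if pred.size != lab.size:
        raise ValueError("predictor and labels must align")
    pos = pred[lab]
    neg = pred[~lab]
    if pos.size < 2 or neg.size < 2:
        raise ValueError("need at least 2 subjects in each class")

    ranks = stats.rankdata(pred)  # midranks handle ties
    auc = (ranks[lab].sum() - pos.size * (pos.size + 1) / 2.0) / (pos.size * neg.size)

    if ci_method == "delong":
        se = np.sqrt(_delong_variance(pos, neg))
        ci_low, ci_high = auc - 1.959963984540054 * se, auc + 1.959963984540054 * se
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        boots = np.empty(n_boot)
        for b in range(n_boot):
            bp = rng.choice(pos, pos.size, replace=True)
            bn = rng.choice(neg, neg.size, replace=True)
            r = stats.rankdata(np.concatenate([bp, bn]))
            boots[b] = (r[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0) / (
                pos.size * neg.size
            )
        ci_low, ci_high = np.quantile(boots, [0.025, 0.975])
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    ci_low = float(np.clip(ci_low, 0.0, 1.0))
    ci_high = float(np.clip(ci_high, 0.0, 1.0))

    # Empirical ROC polyline over all distinct thresholds (>= predicts positive).
    cuts = np.concatenate([[-np.inf], np.unique(pred)])
    sens = np.array([(pos >= c).mean() for c in cuts])
    spec = np.array([(neg < c).mean() for c in cuts])
    curve = pd.DataFrame({"cutoff": cuts, "sensitivity": sens, "specificity": spec})

    eligible = sens >= sens_floor
    if not eligible.any():  # cutoff -inf always has sensitivity 1
        eligible = np.ones_like(eligible, dtype=bool)
    youden = sens + spec - 1.0
    masked = np.where(eligible, youden, -np.inf)
    best = int(np.flatnonzero(masked == masked.max())[-1])  # tie -> most specific
    return RocResult(
        auc=float(auc),
        ci_low=ci_low,
        ci_high=ci_high,
        cutoff=float(cuts[best]),
        sensitivity=float(sens[best]),
        specificity=float(spec[best]),
        n_pos=int(pos.size),
        n_neg=int(neg.size),
        curve=curve,
    )
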