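"""Survival statistics: Harrell's concordance, log-rank tests, Fisher tests.

The concordance index is computed by explicit pair enumeration (a pair is
usable when the subject with the shorter time had an event; tied
predictions contribute 1/2).  Its standard error and the paired comparison
of two predictors both come from the leave-one-subject-out jackknife of the
underlying U-statistic, which is consistent and exact to compute once the
pairwise contributions are tabulated.  One-sided log-rank p-values use the
signed observed-minus-expected statistic's normal tail; the two-sided
version squares it against chi-square(1).  Descriptive Cox summaries (HR,
Wald CI) and Kaplan-Meier medians are delegated to lifelines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CindexResult",
    "concordance_index",
    "compare_cindex",
    "logrank_counts",
    "logrank_one_sided",
    "logrank_two_sided",
    "fisher_one_sided",
    "km_cox_summary",
]


@dataclass
class CindexResult:
    """Concordance estimate with jackknife SE and a test against 0.5."""

    estimate: float
    se: float
    p_value: float
    n: int
    n_comparable: int


def _pair_tables(pred: np.ndarray, time: np.ndarray,
                 event: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Directed comparable-pair indicator and concordance contributions.

    Entry (i, j) is usable when t_i < t_j and subject i had an event; the
    contribution is 1 if pred_i > pred_j, 1/2 on a prediction tie, else 0.
    """
    t_i = time[:, None]
    t_j = time[None, :]
    comparable = (t_i < t_j) & event[:, None]
    p_i = pred[:, None]
    p_j = pred[None, :]
    contrib = np.where(p_i > p_j, 1.0, np.where(p_i == p_j, 0.5, 0.0))
    return comparable, contrib * comparable


def concordance_index(pred, time, event) -> CindexResult:
    """Harrell's c-index with jackknife SE and two-sided p-value vs 0.5."""
    pred = np.asarray(pred, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    n = len(pred)
    comparable, contrib = _pair_tables(pred, time, event)
    W = comparable.sum()
    if W == 0:
        raise ValueError("no comparable pairs")
    S = contrib.sum()
    c = S / W

    # leave-one-out values: removing subject k removes every pair involving k
    w_k = comparable.sum(axis=0) + comparable.sum(axis=1)
    s_k = contrib.sum(axis=0) + contrib.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c_loo = (S - s_k) / (W - w_k)
    c_loo = np.where(W - w_k > 0, c_loo, c)
    se = float(np.sqrt((n - 1) / n * np.sum((c_loo - c_loo.mean()) ** 2)))
    if se > 0:
        p = 2.0 * sps.norm.sf(abs(c - 0.5) / se)
    else:
        p = 1.0 if c == 0.5 else 0.0
    return CindexResult(float(c), se, float(p), n, int(W))


def compare_cindex(pred_a, pred_b, time, event) -> dict:
    """Paired comparison of two predictors' c-indices on shared data.

    Jackknifes the difference of the two pairwise U-statistics; returns the
    difference (a - b), its SE and a two-sided p-value.  Comparing a
    predictor with itself gives p = 1.
    """
    pred_a = np.asarray(pred_a, dtype=float)
    pred_b = np.asarray(pred_b, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    n = len(time)
    comparable, contrib_a = _pair_tables(pred_a, time, event)
    _, contrib_b = _pair_tables(pred_b, time, event)
    W = comparable.sum()
    if W == 0:
        raise ValueError("no comparable pairs")
    Sa, Sb = contrib_a.sum(), contrib_b.sum()
    delta = (Sa - Sb) / W
    w_k = comparable.sum(axis=0) + comparable.sum(axis=1)
    sa_k = contrib_a.sum(axis=0) + contrib_a.sum(axis=1)
    sb_k = contrib_b.sum(axis=0) + contrib_b.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        d_loo = ((Sa - sa_k) - (Sb - sb_k)) / (W - w_k)
    d_loo = np.where(W - w_k > 0, d_loo, delta)
    se = float(np.sqrt((n - 1) / n * np.sum((d_loo - d_loo.mean()) ** 2)))
    if se > 0:
        p = 2.0 * sps.norm.sf(abs(delta) / se)
    else:
        p = 1.0
    return {"delta": float(delta), "se": se, "p_value": float(p)}


# ---------------------------------------------------------------------------
# log-rank


def logrank_counts(time, event, group) -> tuple[float, float, float]:
    """Observed events, expected events and variance for group == 1.

    Standard hypergeometric increments at each distinct event time.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    group = np.asarray(group, dtype=bool)
    obs = exp = var = 0.0
    for t in np.unique(time[event]):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & group).sum()
        d = (event & (time == t)).sum()
        d1 = (event & (time == t) & group).sum()
        obs += d1
        exp += d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return float(obs), float(exp), float(var)


def logrank_two_sided(time, event, group) -> float:
    obs, exp, var = logrank_counts(time, event, group)
    if var <= 0:
        return 1.0
    return float(sps.chi2.sf((obs - exp) ** 2 / var, 1))


def logrank_one_sided(time, event, active) -> float:
    """One-sided log-rank p favoring the active group (fewer events/longer
    survival); small when the active arm does better than expected."""
    obs, exp, var = logrank_counts(time, event, active)
    if var <= 0:
        return 1.0
    z = (obs - exp) / np.sqrt(var)
    return float(sps.norm.cdf(z))


# ---------------------------------------------------------------------------
# Fisher


def fisher_one_sided(x_active, n_active, x_control, n_control):
    """One-sided Fisher exact p for responders(active) > responders(control).

    Exact hypergeometric tail: P(X >= x_active) with the observed margins.
    Accepts scalars or arrays (vectorized over simulations).
    """
    x_a = np.asarray(x_active)
    x_c = np.asarray(x_control)
    p = sps.hypergeom.sf(x_a - 1, n_active + n_control, x_a + x_c, n_active)
    return float(p) if np.ndim(x_active) == 0 else p


# ---------------------------------------------------------------------------
# KM / Cox summaries


def km_cox_summary(time, event, group_labels) -> dict:
    """Two-group survival summary: Cox HR with 95% Wald CI, two-sided
    log-rank p and per-group KM medians.

    The hazard ratio is for the second (lexicographically larger) group
    versus the first.  Raises on a single group or zero events per group.
    """
    from lifelines import CoxPHFitter, KaplanMeierFitter

    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    labels = pd.Series(group_labels).astype(str).to_numpy()
    uniq = sorted(set(labels))
    if len(uniq) != 2:
        raise ValueError(f"need exactly 2 groups, got {uniq}")
    for g in uniq:
        if event[labels == g].sum() == 0:
            raise ValueError(f"group {g!r} has zero events")

    df = pd.DataFrame({"time": time, "event": event.astype(int),
                       "x": (labels == uniq[1]).astype(float)})
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    hr = float(np.exp(cph.params_["x"]))
    ci = cph.confidence_intervals_.loc["x"]
    medians = {}
    for g in uniq:
        km = KaplanMeierFitter()
        km.fit(time[labels == g], event[labels == g])
        med = km.median_survival_time_
        medians[g] = float(med) if np.isfinite(med) else None
    return {
        "hr": hr,
        "hr_ci": (float(np.exp(ci.iloc[0])), float(np.exp(ci.iloc[1]))),
        "logrank_p": logrank_two_sided(time, event, labels == uniq[1]),
        "medians": medians,
        "groups": uniq,
    }
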