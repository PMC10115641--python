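"""Operating characteristics of early-endpoint go/no-go decisions.

Small randomized phase-2 trials are emulated by resampling patients with
replacement from a source cohort (30 per arm by default, 2,000 simulated
trials).  Each trial is scored on early endpoints: the number of molecular
responders (mResp; one-sided Fisher exact), the number of week-6
radiographic responders (RECIST CR/PR; one-sided Fisher exact), early PFS
(one-sided log-rank), and min-p combinations of the ctDNA endpoint with
each radiographic endpoint.  The go cutoff for an endpoint is calibrated as
the target-false-go percentile of the endpoint's p-values over null
(control-vs-control) trials; the true (or realized false) go rate is the
fraction of trials with p below the cutoff.  Combined endpoints are
calibrated on the null distribution of the min-p statistic itself, which
preserves the target false-go rate.

Two enrollment scenarios are supported.  Under instantaneous enrollment all
patients share the same early follow-up horizon (C3D1 day + assay
turnaround, 56 days by default).  Under ramp-up enrollment the calendar
cutoff is the last enrolled patient's C3D1 day plus the turnaround, each
patient's follow-up is truncated at cutoff minus their own enrollment day,
and resampled patient sets must enroll within a 12-month window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .stats import fisher_one_sided, logrank_one_sided

__all__ = [
    "TrialSimConfig",
    "GoRates",
    "make_endpoint_table",
    "simulate_trials",
    "calibrate_go_cutoff",
    "compute_go_rates",
    "apply_enrollment_mode",
    "run_operating_characteristics",
]

ENDPOINTS = ("mresp", "recist", "pfs", "mresp+recist", "mresp+pfs")


@dataclass
class TrialSimConfig:
    n_per_arm: int = 30
    n_sims: int = 2000
    target_false_go: float = 0.15
    endpoints: tuple[str, ...] = ENDPOINTS
    enrollment_mode: str = "instantaneous"   # or "ramp_up"
    turnaround_days: float = 14.0
    c3d1_day: float = 42.0
    early_pfs_horizon_days: float = 56.0     # c3d1_day + turnaround
    enrollment_window_days: float = 365.0
    max_retries: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_arm < 2:
            raise ValueError("n_per_arm must be >= 2")
        if self.n_sims < 100:
            raise ValueError("n_sims must be >= 100")
        if not (0.0 < self.target_false_go < 1.0):
            raise ValueError("target_false_go must lie in (0, 1)")
        if self.enrollment_mode not in ("instantaneous", "ramp_up"):
            raise ValueError(
                f"unknown enrollment mode {self.enrollment_mode!r}")
        unknown = set(self.endpoints) - set(ENDPOINTS)
        if unknown:
            raise ValueError(f"unknown endpoints: {sorted(unknown)}")


@dataclass
class GoRates:
    endpoint: str
    cutoff: float
    true_go_rate: float
    false_go_rate: float
    n_sims: int


def make_endpoint_table(patients: Sequence, calls: pd.Series,
                        response_categories: tuple[str, ...] = ("CR", "PR"),
                        ) -> pd.DataFrame:
    """Per-patient endpoint data for trial resampling.

    ``calls`` maps patient id to a molecular risk call (mResp/mSD/mPD);
    patients without a call (e.g. not at risk at the landmark) count as
    non-responders.  RECIST response is a week-6 category in
    ``response_categories``.
    """
    rows = []
    for p in patients:
        wk6 = next((a for a in p.tumor_assessments if a.week == 6), None)
        rows.append({
            "patient_id": p.patient_id,
            "arm": p.arm,
            "enrollment_day": p.enrollment_day,
            "mresp": calls.get(p.patient_id) == "mResp",
            "recist_response": (wk6 is not None
                                and wk6.category in response_categories),
            "pfs_time": p.survival.pfs_time,
            "pfs_event": p.survival.pfs_event,
        })
    return pd.DataFrame(rows).set_index("patient_id")


def apply_enrollment_mode(pfs_time: np.ndarray, pfs_event: np.ndarray,
                          enrollment_day: np.ndarray, mode: str,
                          config: TrialSimConfig,
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Administratively censor PFS for the chosen enrollment scenario."""
    if mode == "instantaneous":
        horizon = np.full(len(pfs_time), config.early_pfs_horizon_days)
    elif mode == "ramp_up":
        cutoff = enrollment_day.max() + config.c3d1_day + config.turnaround_days
        horizon = cutoff - enrollment_day
    else:
        raise ValueError(f"unknown enrollment mode {mode!r}")
    time = np.minimum(pfs_time, horizon)
    event = pfs_event & (pfs_time <= horizon)
    return time, event


def _sample_arm(rng: np.random.Generator, pool: np.ndarray,
                enrollment: np.ndarray, config: TrialSimConfig) -> np.ndarray:
    """Resample one arm with replacement; under ramp-up enrollment the
    chosen patients' enrollment days must span at most the configured
    window (bounded rejection sampling)."""
    for _ in range(config.max_retries):
        idx = rng.integers(0, len(pool), size=config.n_per_arm)
        chosen = pool[idx]
        if config.enrollment_mode != "ramp_up":
            return chosen
        days = enrollment[chosen]
        if days.max() - days.min() <= config.enrollment_window_days:
            return chosen
    raise RuntimeError(
        "no resampled patient set satisfied the enrollment-window "
        f"constraint in {config.max_retries} retries")


def simulate_trials(table: pd.DataFrame, active_arm: str, control_arm: str,
                    config: TrialSimConfig,
                    rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Resample trials and return one-sided endpoint p-values per trial.

    With ``active_arm == control_arm`` both arms are drawn independently
    from the control pool (the null configuration used for calibration).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    for col in ("arm", "enrollment_day", "mresp", "recist_response",
                "pfs_time", "pfs_event"):
        if col not in table.columns:
            raise ValueError(f"endpoint table lacks column {col!r}")
    arms = table["arm"].to_numpy()
    active_pool = np.flatnonzero(arms == active_arm)
    control_pool = np.flatnonzero(arms == control_arm)
    if len(active_pool) == 0 or len(control_pool) == 0:
        raise ValueError("empty arm pool")

    enrollment = table["enrollment_day"].to_numpy(dtype=float)
    mresp = table["mresp"].to_numpy(dtype=bool)
    recist = table["recist_response"].to_numpy(dtype=bool)
    pfs_t = table["pfs_time"].to_numpy(dtype=float)
    pfs_e = table["pfs_event"].to_numpy(dtype=bool)

    need_pfs = any("pfs" in ep for ep in config.endpoints)
    n = config.n_per_arm
    records = []
    for _ in range(config.n_sims):
        a_idx = _sample_arm(rng, active_pool, enrollment, config)
        c_idx = _sample_arm(rng, control_pool, enrollment, config)
        row: dict[str, float] = {}
        if any("mresp" in ep for ep in config.endpoints):
            row["mresp"] = fisher_one_sided(
                mresp[a_idx].sum(), n, mresp[c_idx].sum(), n)
        if any("recist" in ep for ep in config.endpoints):
            row["recist"] = fisher_one_sided(
                recist[a_idx].sum(), n, recist[c_idx].sum(), n)
        if need_pfs:
            idx = np.concatenate([a_idx, c_idx])
            t, e = apply_enrollment_mode(
                pfs_t[idx], pfs_e[idx], enrollment[idx],
                config.enrollment_mode, config)
            active_mask = np.zeros(2 * n, dtype=bool)
            active_mask[:n] = True
            row["pfs"] = logrank_one_sided(t, e, active_mask)
        if "mresp+recist" in config.endpoints:
            row["mresp+recist"] = min(row["mresp"], row["recist"])
        if "mresp+pfs" in config.endpoints:
            row["mresp+pfs"] = min(row["mresp"], row["pfs"])
        records.append(row)
    return pd.DataFrame(records)


def calibrate_go_cutoff(null_pvalues, target_false_go: float) -> float:
    """Go cutoff: the target percentile (linear interpolation) of null
    p-values; a trial is a Go when its p-value is strictly below it."""
    p = np.asarray(null_pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("null p-value sample is empty")
    return float(np.quantile(p, target_false_go))


def compute_go_rates(active_pvalues, null_pvalues_independent, cutoff: float,
                     endpoint: str = "") -> GoRates:
    a = np.asarray(active_pvalues, dtype=float)
    nn = np.asarray(null_pvalues_independent, dtype=float)
    return GoRates(
        endpoint=endpoint,
        cutoff=float(cutoff),
        true_go_rate=float(np.mean(a < cutoff)),
        false_go_rate=float(np.mean(nn < cutoff)),
        n_sims=len(a),
    )


def run_operating_characteristics(
        table: pd.DataFrame, active_arm: str, control_arm: str,
        config: TrialSimConfig) -> pd.DataFrame:
    """Full procedure: calibrate cutoffs on null trials, evaluate true go
    rates on active-vs-control trials and realized false-go rates on an
    independent set of null trials."""
    rng = np.random.default_rng(config.seed)
    null_cal = simulate_trials(table, control_arm, control_arm, config,
                               rng=np.random.default_rng(rng.integers(2**31)))
    active = simulate_trials(table, active_arm, control_arm, config,
                             rng=np.random.default_rng(rng.integers(2**31)))
    null_ind = simulate_trials(table, control_arm, control_arm, config,
                               rng=np.random.default_rng(rng.integers(2**31)))
    rows = []
    for ep in config.endpoints:
        cutoff = calibrate_go_cutoff(null_cal[ep], config.target_false_go)
        gr = compute_go_rates(active[ep], null_ind[ep], cutoff, endpoint=ep)
        rows.append({"endpoint": ep, "cutoff": gr.cutoff,
                     "true_go_rate": gr.true_go_rate,
                     "false_go_rate": gr.false_go_rate,
                     "n_sims": gr.n_sims, "seed": config.seed})
    return pd.DataFrame(rows)
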