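"""Synthetic randomized-trial cohorts with longitudinal ctDNA and survival.

Generates three-arm trial cohorts in which a latent week-6 response class
(CR/PR, SD or PD) drives both the on-treatment ctDNA trajectory and the
change in radiographic tumor size (SLD), survival times follow a
proportional-hazards model on log baseline ctDNA burden, response class and
treatment arm, and the observation layer draws variant-supporting reads
binomially at a configurable consensus depth so that limit-of-detection
behavior emerges naturally.  CHIP variants are shared between plasma and
matched PBMCs; samples after radiographic progression are missing; a small
fraction of collected samples fail assay QC and carry no variant data.

The generated cohort round-trips through five tab-delimited tables
(patients, samples, variants, pbmc, recist).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .assay import PlasmaSample, ReadSupport, VariantObservation, VISIT_LABELS

__all__ = [
    "CohortConfig",
    "SurvivalRecord",
    "TumorAssessment",
    "SyntheticPatient",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "simulate_survival_features",
    "CohortConfigError",
    "CohortParseError",
]

DEFAULT_VISIT_DAYS = {"BL": 0, "C2D1": 21, "C3D1": 42, "C4D1": 63, "C8D1": 147}

# Gene frequencies loosely matching somatic prevalence in nonsquamous NSCLC
# liquid-biopsy panels (TP53/KRAS/STK11/EGFR dominant).
_GENES = ("TP53", "KRAS", "STK11", "EGFR", "KEAP1", "NF1", "ATM", "MLL3",
          "FAT1", "PIK3CA", "BRAF", "SMARCA4")
_GENE_W = np.array([0.30, 0.16, 0.09, 0.08, 0.07, 0.06, 0.05, 0.05,
                    0.05, 0.04, 0.03, 0.02])


class CohortConfigError(ValueError):
    """Invalid cohort configuration; message names the offending field."""


class CohortParseError(ValueError):
    """Malformed cohort table; message carries file and line number."""


@dataclass
class SurvivalRecord:
    """OS/PFS times in days from randomization, with event flags."""

    os_time: float
    os_event: bool
    pfs_time: float
    pfs_event: bool

    def __post_init__(self) -> None:
        if self.os_time < 0 or self.pfs_time < 0:
            raise ValueError("survival times must be >= 0")


@dataclass
class TumorAssessment:
    """Radiographic assessment: week, sum of longest diameters, category."""

    week: int
    sld: float
    category: str | None  # CR / PR / SD / PD; None at baseline


@dataclass
class CohortConfig:
    """Parameters of the synthetic trial-cohort generator.

    Defaults emulate a three-arm 1:1:1 chemo-immunotherapy trial with plasma
    collections on a 21-day cycle, ~85% baseline ctDNA positivity, class
    multipliers whose cumulative product at C3D1 reproduces mean MTM changes
    of about -70% (CR/PR), -39% (SD) and +54% (PD), lognormal baseline
    allele fractions with a median mean-AF near 1.4%, and ~5,400x consensus
    read depth.
    """

    n_patients: int = 240
    arm_labels: tuple[str, str, str] = ("BCP", "ABCP", "ACP")  # control first
    arm_probs: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    visit_days: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_VISIT_DAYS))
    baseline_positivity: float = 0.85
    response_mix: Mapping[str, float] = field(
        default_factory=lambda: {"CR/PR": 0.35, "SD": 0.55, "PD": 0.10})
    class_trajectory_multipliers: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "CR/PR": {"C2D1": 0.55, "C3D1": 0.55, "C4D1": 0.75, "C8D1": 0.85},
            "SD": {"C2D1": 0.78, "C3D1": 0.78, "C4D1": 0.92, "C8D1": 1.05},
            "PD": {"C2D1": 1.24, "C3D1": 1.24, "C4D1": 1.30, "C8D1": 1.35},
        })
    hazard_coefficients: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "os": {"log10_burden": 0.35, "SD": 0.40, "PD": 1.10},
            "pfs": {"log10_burden": 0.30, "SD": 0.60, "PD": 1.60},
        })
    arm_effects: Mapping[str, float] = field(
        default_factory=lambda: {"BCP": 0.0, "ABCP": -0.25, "ACP": -0.22})
    #: extra probability mass moved from SD/PD into CR/PR on active arms,
    #: giving the treatment effect a response-rate footprint
    arm_response_boost: Mapping[str, float] = field(
        default_factory=lambda: {"BCP": 0.0, "ABCP": 0.08, "ACP": 0.06})
    mutation_count_distribution: Mapping[str, float] = field(
        default_factory=lambda: {"mean": 5.0})
    chip_rate: float = 0.64
    chip_extra_mean: float = 0.8  # CHIP count = 1 + Poisson(this), given carrier
    read_depth: int = 5400
    cfdna_conc_distribution: Mapping[str, float] = field(
        default_factory=lambda: {"log_mean": math.log(10.0), "log_sd": 0.8})
    baseline_af_distribution: Mapping[str, float] = field(
        default_factory=lambda: {"log_mean": math.log(0.014), "log_sd": 1.2})
    af_noise_sd: float = 0.35       # per-visit lognormal noise on burden
    sld_noise_sd: float = 12.0      # percent-points noise on week-6 SLD change
    burden_sld_rho: float = 0.4     # shared factor: baseline burden vs SLD
    os_baseline_median_days: float = 820.0
    pfs_baseline_median_days: float = 330.0
    followup_days: float = 1250.0
    censoring_mean_days: float = 2400.0
    dropout_rule: bool = True
    qc_fail_rate: float = 0.03
    enrollment_window_days: int = 365
    seed: int = 0

    def validate(self) -> None:
        def _prob(name: str, value: float) -> None:
            if not (0.0 <= value <= 1.0):
                raise CohortConfigError(f"{name} must lie in [0, 1], got {value}")

        if self.n_patients < 0:
            raise CohortConfigError("n_patients must be >= 0")
        if len(self.arm_labels) != 3 or len(self.arm_probs) != 3:
            raise CohortConfigError("arm_labels and arm_probs must have length 3")
        if abs(sum(self.arm_probs) - 1.0) > 1e-12:
            raise CohortConfigError("arm_probs must sum to 1")
        if abs(sum(self.response_mix.values()) - 1.0) > 1e-12:
            raise CohortConfigError("response_mix must sum to 1")
        for p in self.arm_probs:
            _prob("arm_probs", p)
        for p in self.response_mix.values():
            _prob("response_mix", p)
        _prob("baseline_positivity", self.baseline_positivity)
        _prob("chip_rate", self.chip_rate)
        _prob("qc_fail_rate", self.qc_fail_rate)
        days = list(self.visit_days.values())
        if days != sorted(days) or len(set(days)) != len(days):
            raise CohortConfigError("visit_days must be strictly increasing")
        if self.visit_days.get("BL", None) != 0:
            raise CohortConfigError("visit_days must map BL to 0")
        if self.read_depth <= 0:
            raise CohortConfigError("read_depth must be > 0")
        if self.enrollment_window_days < 0:
            raise CohortConfigError("enrollment_window_days must be >= 0")


@dataclass
class SyntheticPatient:
    patient_id: str
    arm: str
    latent_class: str
    enrollment_day: int
    baseline_covariates: dict
    plasma_samples: list[PlasmaSample]
    pbmc_calls: list[str]
    survival: SurvivalRecord
    tumor_assessments: list[TumorAssessment]


def _zt_poisson(rng: np.random.Generator, mean: float) -> int:
    """Zero-truncated Poisson draw (rejection; mean is the untruncated mean)."""
    while True:
        k = rng.poisson(mean)
        if k > 0:
            return int(k)


def _shifted_mix(mix: Mapping[str, float], boost: float) -> tuple[list[str], np.ndarray]:
    """Move `boost` probability mass from SD/PD into CR/PR, proportionally."""
    labels = list(mix)
    p = np.array([mix[k] for k in labels], dtype=float)
    if boost:
        i_resp = labels.index("CR/PR")
        others = [i for i in range(len(labels)) if i != i_resp]
        avail = p[others].sum()
        take = min(boost, avail)
        p[others] -= take * p[others] / avail
        p[i_resp] += take
    return labels, p / p.sum()


def generate_cohort(config: CohortConfig) -> list[SyntheticPatient]:
    """Generate a synthetic trial cohort; deterministic for a fixed seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    visits = list(config.visit_days)
    on_tx_visits = [v for v in visits if v != "BL"]
    patients: list[SyntheticPatient] = []

    for idx in range(config.n_patients):
        pid = f"P{idx:04d}"
        arm = str(rng.choice(config.arm_labels, p=config.arm_probs))
        enrollment_day = int(rng.integers(0, max(config.enrollment_window_days, 1)))

        # latent response class (arm can shift mass toward CR/PR)
        labels, mix = _shifted_mix(
            config.response_mix, config.arm_response_boost.get(arm, 0.0))
        latent_class = str(rng.choice(labels, p=mix))

        # shared factor couples baseline tumor size (SLD) and ctDNA burden
        rho = config.burden_sld_rho
        z_shared = rng.standard_normal()
        z_sld = rho * z_shared + math.sqrt(1 - rho * rho) * rng.standard_normal()
        z_af = rho * z_shared + math.sqrt(1 - rho * rho) * rng.standard_normal()
        baseline_sld = float(np.exp(math.log(70.0) + 0.5 * z_sld))

        covariates = {
            "age": int(np.clip(round(rng.normal(63, 9)), 30, 88)),
            "sex": "M" if rng.random() < 0.6 else "F",
            "ecog": int(rng.random() < 0.6),
            "smoker": "y" if rng.random() < 0.8 else "n",
            "n_met_sites": int(1 + rng.poisson(1.2)),
            "pdl1_high": int(rng.random() < 0.45),
            "baseline_sld": baseline_sld,
        }

        afd = config.baseline_af_distribution
        mean_af = float(np.exp(afd["log_mean"] + afd["log_sd"] * z_af))
        cfd = config.cfdna_conc_distribution
        cfdna_bl = float(np.exp(rng.normal(cfd["log_mean"], cfd["log_sd"])))

        # somatic variants (85% of patients carry at least one)
        somatic: list[tuple[str, str, bool, float]] = []
        if rng.random() < config.baseline_positivity:
            n_som = _zt_poisson(rng, config.mutation_count_distribution["mean"])
            genes = rng.choice(_GENES, size=n_som, p=_GENE_W / _GENE_W.sum())
            for j, g in enumerate(genes):
                af = float(np.clip(
                    mean_af * np.exp(rng.normal(0.0, 0.6)), 1e-6, 0.85))
                somatic.append((f"{pid}:{g}:s{j}", str(g), rng.random() < 0.6, af))

        # CHIP variants: present in plasma at all visits and called in PBMCs
        chip: list[tuple[str, str, bool, float]] = []
        if rng.random() < config.chip_rate:
            n_chip = 1 + int(rng.poisson(config.chip_extra_mean))
            genes = rng.choice(_GENES, size=n_chip, p=_GENE_W / _GENE_W.sum())
            for j, g in enumerate(genes):
                af = float(np.clip(np.exp(rng.normal(math.log(0.013), 1.0)),
                                   1e-5, 0.5))
                chip.append((f"{pid}:{g}:c{j}", str(g), False, af))

        true_mtm_bl = (np.mean([a for *_ignore, a in somatic]) * cfdna_bl / 0.0033
                       if somatic else 0.0)

        # survival via exponential proportional hazards; the linear predictor
        # is centered at the cohort-typical burden and response mix so the
        # configured baseline medians are the realized cohort-level medians
        hz = config.hazard_coefficients
        arm_eff = config.arm_effects.get(arm, 0.0)
        burden_center = 1.4  # typical log10(baseline MTM + 1)

        def _lp(ep: str) -> float:
            co = hz[ep]
            class_center = sum(config.response_mix[k] * co.get(k, 0.0)
                               for k in config.response_mix)
            lp = co.get("log10_burden", 0.0) * (
                math.log10(true_mtm_bl + 1.0) - burden_center)
            lp += co.get(latent_class, 0.0) - class_center
            return lp + arm_eff

        t_death = rng.exponential(
            config.os_baseline_median_days / math.log(2) * math.exp(-_lp("os")))
        t_prog = rng.exponential(
            config.pfs_baseline_median_days / math.log(2) * math.exp(-_lp("pfs")))
        cens = min(config.followup_days, rng.exponential(config.censoring_mean_days))
        os_time = min(t_death, cens)
        os_event = t_death <= cens
        pfs_raw = min(t_prog, t_death)
        pfs_time = min(pfs_raw, cens)
        pfs_event = pfs_raw <= cens
        survival = SurvivalRecord(os_time, bool(os_event),
                                  pfs_time, bool(pfs_event))

        # per-visit burden multipliers with shared lognormal noise; the C3D1
        # noise term is reused below so SLD change correlates with ctDNA change
        mults = config.class_trajectory_multipliers[latent_class]
        cum = 1.0
        cum_by_visit: dict[str, float] = {"BL": 1.0}
        visit_noise: dict[str, float] = {"BL": 0.0}
        for v in on_tx_visits:
            cum *= mults.get(v, 1.0)
            z_v = rng.standard_normal()
            visit_noise[v] = z_v
            cum_by_visit[v] = cum * math.exp(config.af_noise_sd * z_v)

        # week-6 SLD change: class mean + shared trajectory noise + residual
        sld_class_mean = {"CR/PR": -45.0, "SD": -10.0, "PD": 30.0}[latent_class]
        pct_sld = (sld_class_mean + 10.0 * visit_noise.get("C3D1", 0.0)
                   + rng.normal(0.0, config.sld_noise_sd))
        pct_sld = max(pct_sld, -100.0)
        week6_sld = baseline_sld * (1.0 + pct_sld / 100.0)
        if pct_sld <= -100.0 + 1e-9:
            category = "CR"
        elif pct_sld <= -30.0:
            category = "PR"
        elif pct_sld >= 20.0:
            category = "PD"
        else:
            category = "SD"
        assessments = [TumorAssessment(0, baseline_sld, None)]
        if os_time > 42 or not os_event:
            assessments.append(TumorAssessment(6, week6_sld, category))

        samples: list[PlasmaSample] = []
        for v in visits:
            day = config.visit_days[v]
            if day > 0 and config.dropout_rule and pfs_event and day > pfs_time:
                continue  # off study at progression: sample never collected
            qc_pass = rng.random() >= config.qc_fail_rate
            cfdna = float(np.clip(
                cfdna_bl * np.exp(rng.normal(0.0, 0.25)), 0.3, None))
            obs: list[VariantObservation] = []
            mult = cum_by_visit[v]
            for vid, gene, patho, af_bl in somatic:
                af = float(np.clip(af_bl * mult * np.exp(rng.normal(0.0, 0.15)),
                                   0.0, 0.9))
                nrv = int(rng.binomial(config.read_depth, af))
                obs.append(VariantObservation(
                    vid, gene, patho, v,
                    ReadSupport(nrv, config.read_depth - nrv,
                                int(rng.poisson(5)))))
            for vid, gene, patho, af_c in chip:
                af = float(np.clip(af_c * np.exp(rng.normal(0.0, 0.1)), 0.0, 0.9))
                nrv = int(rng.binomial(config.read_depth, af))
                obs.append(VariantObservation(
                    vid, gene, patho, v,
                    ReadSupport(nrv, config.read_depth - nrv,
                                int(rng.poisson(5)))))
            if not qc_pass:
                obs = []
            samples.append(PlasmaSample(pid, v, float(day), cfdna,
                                        obs, qc_pass))

        patients.append(SyntheticPatient(
            patient_id=pid,
            arm=arm,
            latent_class=latent_class,
            enrollment_day=enrollment_day,
            baseline_covariates=covariates,
            plasma_samples=samples,
            pbmc_calls=[vid for vid, *_ in chip],
            survival=survival,
            tumor_assessments=assessments,
        ))
    return patients


# ---------------------------------------------------------------------------
# tabular round trip


def cohort_to_frames(cohort: Sequence[SyntheticPatient]) -> dict[str, pd.DataFrame]:
    """Flatten a cohort into the five on-disk tables."""
    pat_rows, samp_rows, var_rows, pbmc_rows, rec_rows = [], [], [], [], []
    for p in cohort:
        pat_rows.append({
            "patient_id": p.patient_id, "arm": p.arm,
            "latent_class": p.latent_class,
            "enrollment_day": p.enrollment_day,
            **p.baseline_covariates,
            "os_time": p.survival.os_time, "os_event": int(p.survival.os_event),
            "pfs_time": p.survival.pfs_time,
            "pfs_event": int(p.survival.pfs_event),
        })
        for s in p.plasma_samples:
            samp_rows.append({
                "patient_id": p.patient_id, "visit": s.visit,
                "collection_day": s.collection_day,
                "cfdna_conc": s.cfdna_conc, "qc_pass": int(s.qc_pass),
            })
            for o in s.observations:
                var_rows.append({
                    "patient_id": p.patient_id, "visit": s.visit,
                    "variant_id": o.variant_id, "gene": o.gene,
                    "pathogenic": int(o.pathogenic),
                    "nrv": o.read_support.nrv, "nrr": o.read_support.nrr,
                    "nre": o.read_support.nre,
                })
        for vid in p.pbmc_calls:
            pbmc_rows.append({"patient_id": p.patient_id, "variant_id": vid})
        for a in p.tumor_assessments:
            rec_rows.append({
                "patient_id": p.patient_id, "week": a.week, "sld": a.sld,
                "category": a.category if a.category is not None else "",
            })
    return {
        "patients": pd.DataFrame(pat_rows, columns=[
            "patient_id", "arm", "latent_class", "enrollment_day", "age",
            "sex", "ecog", "smoker", "n_met_sites", "pdl1_high",
            "baseline_sld", "os_time", "os_event", "pfs_time", "pfs_event"]),
        "samples": pd.DataFrame(samp_rows, columns=[
            "patient_id", "visit", "collection_day", "cfdna_conc", "qc_pass"]),
        "variants": pd.DataFrame(var_rows, columns=[
            "patient_id", "visit", "variant_id", "gene", "pathogenic",
            "nrv", "nrr", "nre"]),
        "pbmc": pd.DataFrame(pbmc_rows, columns=["patient_id", "variant_id"]),
        "recist": pd.DataFrame(rec_rows, columns=[
            "patient_id", "week", "sld", "category"]),
    }


def write_cohort(cohort: Sequence[SyntheticPatient], path: str | Path,
                 metadata: Mapping[str, str] | None = None) -> None:
    """Write a cohort to `path` as five tab-delimited tables."""
    from .io import write_table  # local import avoids a cycle

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for name, df in cohort_to_frames(cohort).items():
        write_table(df, path / f"{name}.tsv", metadata or {})


def read_cohort(path: str | Path) -> list[SyntheticPatient]:
    """Read a cohort previously written by :func:`write_cohort`."""
    from .io import read_table

    path = Path(path)
    frames = {name: read_table(path / f"{name}.tsv")
              for name in ("patients", "samples", "variants", "pbmc", "recist")}
    return frames_to_cohort(frames, source=path)


def frames_to_cohort(frames: Mapping[str, pd.DataFrame],
                     source: Path | None = None) -> list[SyntheticPatient]:
    pats, samps = frames["patients"], frames["samples"]
    vars_, pbmc, rec = frames["variants"], frames["pbmc"], frames["recist"]
    for i, visit in enumerate(samps["visit"], start=2):
        if visit not in VISIT_LABELS:
            where = f"{source / 'samples.tsv'}" if source else "samples"
            raise CohortParseError(
                f"{where}: unknown visit label {visit!r} at line {i}")
    for i, visit in enumerate(vars_["visit"], start=2):
        if visit not in VISIT_LABELS:
            where = f"{source / 'variants.tsv'}" if source else "variants"
            raise CohortParseError(
                f"{where}: unknown visit label {visit!r} at line {i}")

    var_groups = {k: g for k, g in vars_.groupby(["patient_id", "visit"],
                                                 sort=False)}
    cohort: list[SyntheticPatient] = []
    for _, row in pats.iterrows():
        pid = row["patient_id"]
        samples = []
        for _, s in samps[samps["patient_id"] == pid].iterrows():
            obs = []
            g = var_groups.get((pid, s["visit"]))
            if g is not None:
                for _, v in g.iterrows():
                    obs.append(VariantObservation(
                        v["variant_id"], v["gene"], bool(v["pathogenic"]),
                        v["visit"],
                        ReadSupport(int(v["nrv"]), int(v["nrr"]),
                                    int(v["nre"]))))
            samples.append(PlasmaSample(
                pid, s["visit"], float(s["collection_day"]),
                float(s["cfdna_conc"]), obs, bool(s["qc_pass"])))
        assessments = [
            TumorAssessment(int(a["week"]), float(a["sld"]),
                            None if (pd.isna(a["category"]) or a["category"] == "")
                            else a["category"])
            for _, a in rec[rec["patient_id"] == pid].iterrows()]
        cohort.append(SyntheticPatient(
            patient_id=pid, arm=row["arm"], latent_class=row["latent_class"],
            enrollment_day=int(row["enrollment_day"]),
            baseline_covariates={
                "age": int(row["age"]), "sex": row["sex"],
                "ecog": int(row["ecog"]), "smoker": row["smoker"],
                "n_met_sites": int(row["n_met_sites"]),
                "pdl1_high": int(row["pdl1_high"]),
                "baseline_sld": float(row["baseline_sld"]),
            },
            plasma_samples=samples,
            pbmc_calls=list(pbmc[pbmc["patient_id"] == pid]["variant_id"]),
            survival=SurvivalRecord(
                float(row["os_time"]), bool(row["os_event"]),
                float(row["pfs_time"]), bool(row["pfs_event"])),
            tumor_assessments=assessments,
        ))
    return cohort


# ---------------------------------------------------------------------------
# simple survival + feature simulators for model validation


def simulate_survival_features(
    n: int,
    p: int,
    informative: Mapping[int, float] | None = None,
    censoring: float = 0.3,
    baseline_median_days: float = 365.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Standard-normal features with exponential proportional-hazards survival.

    ``informative`` maps column index -> log hazard ratio per IQR of the
    feature (an IQR of a standard normal is ~1.349 units).  Remaining
    columns are pure noise.  ``censoring`` sets the approximate fraction of
    independently censored records.  Returns ``(X, records)`` where
    ``records`` has os_time / os_event columns (days).
    """
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    iqr_std_normal = 1.3489795003921634
    beta = np.zeros(p)
    for j, loghr in (informative or {}).items():
        beta[j] = loghr / iqr_std_normal
    rate0 = math.log(2) / baseline_median_days
    t = rng.exponential(1.0 / (rate0 * np.exp(X @ beta)))
    if censoring > 0:
        c = rng.exponential((1 - censoring) / (censoring * rate0), size=n)
    else:
        c = np.full(n, np.inf)
    time = np.minimum(t, c)
    event = t <= c
    ids = [f"S{i:04d}" for i in range(n)]
    Xdf = pd.DataFrame(X, index=ids,
                       columns=[f"f{j}" for j in range(p)])
    rec = pd.DataFrame({"os_time": time, "os_event": event,
                        "pfs_time": time, "pfs_event": event}, index=ids)
    return Xdf, rec
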