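"""ctDNA metric derivation and landmark feature-matrix assembly.

Per-visit *level* metrics summarize one processed plasma sample (mean/max/
sum allele fraction, MTM, mutation counts, cfDNA concentration, detection
indicator); *change* metrics compare an on-treatment sample to baseline
(absolute, percent and log-fold change per level metric, a clearance
indicator at MTM < 1, the time-weighted MTM AUC to date, and the on-treatment
maximum).  A landmark feature matrix stacks level metrics for every visit up
to the landmark and change metrics for every on-treatment visit up to the
landmark, with columns qualified as ``VISIT:metric`` / ``VISIT_change:metric``.

Missing data policy: a patient contributes a row whenever a sample-collection
record exists for the landmark visit; cells for QC-failed or uncollected
earlier visits are missing and later imputed with the fit-population median
of the feature.  Features are scaled by their fit-population interquartile
range (linear-interpolation quartiles); constant features pass through
unscaled with a warning.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .assay import PlasmaSample
from .cohort import DEFAULT_VISIT_DAYS, SyntheticPatient

__all__ = [
    "MetricCatalog",
    "FeatureMatrix",
    "default_catalog",
    "derive_level_metrics",
    "derive_change_metrics",
    "assemble_feature_matrix",
    "impute_fit",
    "impute_missing",
    "iqr_fit",
    "iqr_apply",
    "AllMissingError",
]

NAN = float("nan")

LevelFn = Callable[[PlasmaSample], float]
ChangeFn = Callable[[PlasmaSample, PlasmaSample, Sequence[PlasmaSample]], float]


class AllMissingError(ValueError):
    """A feature is missing for the entire fit population."""


@dataclass
class MetricCatalog:
    """Named level and change metrics; names must be unique within each map."""

    level: Mapping[str, LevelFn]
    change: Mapping[str, ChangeFn]


@dataclass
class FeatureMatrix:
    """Patients x features with a missingness mask and optional scalers."""

    values: pd.DataFrame
    mask: pd.DataFrame          # True where the cell was originally missing
    scalers: dict | None = None
    fit_tag: str = "unscaled"

    @property
    def patient_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)


# ---------------------------------------------------------------------------
# level metrics


def _pos_afs(s: PlasmaSample) -> list[float]:
    return [o.censored_af for o in s.positive_somatic()
            if o.censored_af is not None and not math.isnan(o.censored_af)]


def _mtm(s: PlasmaSample) -> float:
    return s.mtm if s.mtm is not None else NAN


def default_catalog() -> MetricCatalog:
    """The default metric catalog (11 level + 15 change metrics).

    Covers the metric families used for longitudinal ctDNA modeling: allele
    fraction summaries, MTM, mutation counts, cfDNA concentration, detection
    and clearance indicators, and the time-weighted MTM AUC.
    """
    level: dict[str, LevelFn] = {
        "mean_af": lambda s: float(np.mean(_pos_afs(s))) if _pos_afs(s) else 0.0,
        "median_af": lambda s: float(np.median(_pos_afs(s))) if _pos_afs(s) else 0.0,
        "max_af": lambda s: float(np.max(_pos_afs(s))) if _pos_afs(s) else 0.0,
        "sum_af": lambda s: float(np.sum(_pos_afs(s))),
        "mtm": _mtm,
        "log10_mtm": lambda s: math.log10(_mtm(s) + 1.0),
        "n_mut": lambda s: float(len(s.positive_somatic())),
        "n_path_mut": lambda s: float(
            sum(1 for o in s.positive_somatic() if o.pathogenic)),
        "cfdna_conc": lambda s: s.cfdna_conc,
        "log10_cfdna": lambda s: math.log10(s.cfdna_conc + 1.0),
        "detected": lambda s: 1.0 if s.positive_somatic() else 0.0,
    }

    def _abs(metric: str) -> ChangeFn:
        fn = level[metric]
        return lambda bl, tx, hist: fn(tx) - fn(bl)

    def _pct(metric: str) -> ChangeFn:
        fn = level[metric]

        def inner(bl, tx, hist):
            b = fn(bl)
            if b == 0 or math.isnan(b):
                return NAN
            return 100.0 * (fn(tx) - b) / b

        return inner

    def _lfc(metric: str) -> ChangeFn:
        fn = level[metric]
        return lambda bl, tx, hist: (math.log10(fn(tx) + 1.0)
                                     - math.log10(fn(bl) + 1.0))

    change: dict[str, ChangeFn] = {}
    for m in ("mtm", "mean_af", "n_mut", "cfdna_conc"):
        change[f"abs_{m}"] = _abs(m)
        change[f"pct_{m}"] = _pct(m)
        change[f"lfc_{m}"] = _lfc(m)
    change["clearance"] = lambda bl, tx, hist: 1.0 if _mtm(tx) < 1.0 else 0.0
    change["auc_mtm"] = _auc_mtm
    change["max_mtm_on_tx"] = _max_mtm_on_tx
    return MetricCatalog(level=level, change=change)


def _auc_mtm(bl: PlasmaSample, tx: PlasmaSample,
             history: Sequence[PlasmaSample]) -> float:
    """Time-weighted trapezoidal mean of MTM from baseline through `tx`."""
    pts = sorted(
        [(s.collection_day, s.mtm) for s in history
         if s.collection_day <= tx.collection_day and s.qc_pass
         and s.mtm is not None],
        key=lambda t: t[0])
    if len(pts) < 2:
        return NAN
    days = np.array([d for d, _ in pts])
    vals = np.array([v for _, v in pts])
    span = days[-1] - days[0]
    if span <= 0:
        return NAN
    return float(np.trapezoid(vals, days) / span)


def _max_mtm_on_tx(bl: PlasmaSample, tx: PlasmaSample,
                   history: Sequence[PlasmaSample]) -> float:
    vals = [s.mtm for s in history
            if 0 < s.collection_day <= tx.collection_day and s.qc_pass
            and s.mtm is not None]
    return float(max(vals)) if vals else NAN


def derive_level_metrics(sample: PlasmaSample,
                         catalog: MetricCatalog) -> dict[str, float]:
    """One value per catalog level metric; QC-failed samples yield all-missing."""
    if not sample.qc_pass:
        return {name: NAN for name in catalog.level}
    return {name: float(fn(sample)) for name, fn in catalog.level.items()}


def derive_change_metrics(bl: PlasmaSample, tx: PlasmaSample,
                          history: Sequence[PlasmaSample],
                          catalog: MetricCatalog) -> dict[str, float]:
    """Change metrics for an on-treatment sample relative to baseline."""
    if not tx.qc_pass:
        return {name: NAN for name in catalog.change}
    out = {}
    for name, fn in catalog.change.items():
        if not bl.qc_pass and name not in ("clearance",):
            out[name] = NAN
        else:
            out[name] = float(fn(bl, tx, history))
    return out


# ---------------------------------------------------------------------------
# landmark assembly


def assemble_feature_matrix(
    patients: Sequence[SyntheticPatient],
    landmark_visit: str,
    catalog: MetricCatalog,
    include_clinical: bool = False,
    visit_days: Mapping[str, int] | None = None,
) -> FeatureMatrix:
    """Assemble the landmark feature matrix for processed patients.

    A patient is a row iff a sample-collection record exists for the
    landmark visit (even when that sample failed QC).  Columns are the level
    metrics of every visit up to the landmark and the change metrics of
    every on-treatment visit up to the landmark, optionally followed by
    clinical covariates (with week-6 tumor-size features for C3D1 runs).
    """
    visit_days = dict(visit_days or DEFAULT_VISIT_DAYS)
    if landmark_visit not in visit_days:
        raise ValueError(f"unknown landmark visit {landmark_visit!r}")
    visits = [v for v in visit_days
              if visit_days[v] <= visit_days[landmark_visit]]
    on_tx = [v for v in visits if visit_days[v] > 0]

    rows: dict[str, dict[str, float]] = {}
    for p in patients:
        by_visit = {s.visit: s for s in p.plasma_samples}
        if landmark_visit not in by_visit:
            continue
        row: dict[str, float] = {}
        bl = by_visit.get("BL")
        for v in visits:
            s = by_visit.get(v)
            vals = (derive_level_metrics(s, catalog) if s is not None
                    else {n: NAN for n in catalog.level})
            row.update({f"{v}:{n}": x for n, x in vals.items()})
        for v in on_tx:
            s = by_visit.get(v)
            if s is None or bl is None:
                vals = {n: NAN for n in catalog.change}
            else:
                vals = derive_change_metrics(bl, s, p.plasma_samples, catalog)
            row.update({f"{v}_change:{n}": x for n, x in vals.items()})
        if include_clinical:
            cov = p.baseline_covariates
            row.update({
                "clin:age": float(cov.get("age", NAN)),
                "clin:sex_male": 1.0 if cov.get("sex") == "M" else 0.0,
                "clin:ecog": float(cov.get("ecog", NAN)),
                "clin:smoker": 1.0 if cov.get("smoker") == "y" else 0.0,
                "clin:n_met_sites": float(cov.get("n_met_sites", NAN)),
                "clin:pdl1_high": float(cov.get("pdl1_high", NAN)),
                "clin:baseline_sld": float(cov.get("baseline_sld", NAN)),
            })
            if landmark_visit == "C3D1":
                wk6 = next((a for a in p.tumor_assessments if a.week == 6),
                           None)
                bl_sld = float(cov.get("baseline_sld", NAN))
                w6 = wk6.sld if wk6 is not None else NAN
                row["clin:week6_sld"] = w6
                row["clin:sld_change"] = w6 - bl_sld
                row["clin:sld_pct_change"] = (
                    100.0 * (w6 - bl_sld) / bl_sld if bl_sld else NAN)
        rows[p.patient_id] = row

    values = pd.DataFrame.from_dict(rows, orient="index")
    values.index.name = "patient_id"
    return FeatureMatrix(values=values, mask=values.isna())


# ---------------------------------------------------------------------------
# imputation and IQR scaling


def impute_fit(matrix: FeatureMatrix,
               fit_ids: Sequence[str] | None = None) -> pd.Series:
    """Per-feature medians over the fit population (errors on all-missing)."""
    sub = matrix.values if fit_ids is None else matrix.values.loc[list(fit_ids)]
    if sub.empty:
        raise AllMissingError("empty fit population")
    medians = sub.median(axis=0, skipna=True)
    bad = medians.index[medians.isna()].tolist()
    if bad:
        raise AllMissingError(
            f"features missing for the entire fit population: {bad}")
    return medians


def impute_missing(matrix: FeatureMatrix,
                   fit_ids: Sequence[str] | None = None,
                   medians: pd.Series | None = None) -> FeatureMatrix:
    """Replace missing cells with fit-population medians; keep the mask.

    Observed cells are untouched.  Pass frozen ``medians`` to apply a
    training-time imputer to test or external data.
    """
    if medians is None:
        medians = impute_fit(matrix, fit_ids)
    filled = matrix.values.fillna(medians)
    scalers = dict(matrix.scalers or {})
    scalers["medians"] = medians
    return replace(matrix, values=filled, scalers=scalers)


def iqr_fit(matrix: FeatureMatrix | pd.DataFrame,
            fit_ids: Sequence[str] | None = None) -> dict:
    """Per-feature interquartile ranges (linear-interpolation quartiles)."""
    values = matrix.values if isinstance(matrix, FeatureMatrix) else matrix
    sub = values if fit_ids is None else values.loc[list(fit_ids)]
    q75 = sub.quantile(0.75, interpolation="linear")
    q25 = sub.quantile(0.25, interpolation="linear")
    iqr = (q75 - q25).astype(float)
    constant = iqr.index[(iqr == 0) | iqr.isna()].tolist()
    if constant:
        warnings.warn(
            f"constant features pass through unscaled: {constant}",
            stacklevel=2)
    iqr[(iqr == 0) | iqr.isna()] = 1.0
    return {"iqr": iqr, "constant": constant}


def iqr_apply(matrix: FeatureMatrix, scalers: dict) -> FeatureMatrix:
    """Divide each feature by its (training) IQR."""
    scaled = matrix.values / scalers["iqr"]
    merged = dict(matrix.scalers or {})
    merged.update(scalers)
    return replace(matrix, values=scaled, scalers=merged, fit_tag="scaled")
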