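"""End-to-end pipeline orchestration over the library modules.

Chains cohort simulation, assay post-processing, landmark feature
derivation, elastic-net model training with threshold selection, held-back
evaluation and trial-simulation into file-based stages driven by one YAML
config.  Every stage threads the global seed and stamps its outputs with
the package version, seed and a config hash.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io
from .assay import PresumedNormalPanel, process_sample
from .cohort import CohortConfig, SyntheticPatient, generate_cohort, write_cohort
from .features import FeatureMatrix, assemble_feature_matrix, default_catalog
from .stats import km_cox_summary
from .survival import (
    ElasticNetConfig,
    FinalModel,
    SubgroupSizeError,
    call_molecular_response,
    concordance_index,
    fit_final_model,
    landmark_rebaseline,
    loocv_elastic_net,
    rank_features,
    select_mpd_threshold,
    select_mresp_threshold,
    top_features,
)
from .trialsim import TrialSimConfig, make_endpoint_table, run_operating_characteristics

log = logging.getLogger("ctdnakit")

__all__ = [
    "PipelineConfig",
    "synthetic_normal_panel",
    "process_cohort",
    "split_cohort",
    "recist_series",
    "landmark_days_for",
    "survival_records",
    "train_model",
    "run_all",
]


@dataclass
class PipelineConfig:
    """Configuration of the full pipeline run."""

    outdir: str = "out"
    seed: int = 0
    cohort: dict = field(default_factory=dict)
    landmark_visit: str = "C3D1"
    endpoint: str = "os"
    include_clinical: bool = False
    train_fraction: float = 0.5
    elastic_net: dict = field(default_factory=dict)
    durable_horizon_days: float = 1095.0
    trial_sim: dict = field(default_factory=dict)
    panel_size: int = 400

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def meta(self) -> dict:
        # hash the scientific configuration only, not the output location
        payload = dataclasses.asdict(self)
        payload.pop("outdir", None)
        return {"seed": self.seed, "config_hash": io.config_hash(payload)}


def synthetic_normal_panel(seed: int, size: int = 400) -> PresumedNormalPanel:
    """Pooled presumed-normal background: small exponential-tailed VAFs.

    Synthetic stand-in for the background VAF distribution measured in
    presumed-normal plasma samples.
    """
    rng = np.random.default_rng([seed, 911])
    vafs = np.clip(rng.exponential(3e-4, size=size), 0.0, 0.005)
    return PresumedNormalPanel(pooled=vafs)


def process_cohort(cohort: Sequence[SyntheticPatient],
                   panel: PresumedNormalPanel) -> list[SyntheticPatient]:
    """Run assay post-processing on every plasma sample of every patient."""
    out = []
    for p in cohort:
        pbmc_ids = frozenset(p.pbmc_calls)
        samples = [process_sample(s, panel, pbmc_positive_ids=pbmc_ids)
                   for s in p.plasma_samples]
        out.append(dataclasses.replace(p, plasma_samples=samples))
    return out


def split_cohort(cohort: Sequence[SyntheticPatient], train_fraction: float,
                 seed: int) -> pd.Series:
    """Random split stratified by arm; returns patient -> 'train'/'test'."""
    rng = np.random.default_rng([seed, 37])
    assignment: dict[str, str] = {}
    by_arm: dict[str, list[str]] = {}
    for p in cohort:
        by_arm.setdefault(p.arm, []).append(p.patient_id)
    for arm_ids in by_arm.values():
        ids = np.array(sorted(arm_ids))
        rng.shuffle(ids)
        n_train = int(round(train_fraction * len(ids)))
        for pid in ids[:n_train]:
            assignment[pid] = "train"
        for pid in ids[n_train:]:
            assignment[pid] = "test"
    return pd.Series(assignment, name="split")


def recist_series(cohort: Sequence[SyntheticPatient]) -> pd.Series:
    """Week-6 radiographic category per patient (NaN when unassessed)."""
    vals = {}
    for p in cohort:
        wk6 = next((a for a in p.tumor_assessments if a.week == 6), None)
        vals[p.patient_id] = wk6.category if wk6 is not None else np.nan
    return pd.Series(vals, name="recist")


def landmark_days_for(cohort: Sequence[SyntheticPatient],
                      landmark_visit: str) -> pd.Series:
    days = {}
    for p in cohort:
        s = next((s for s in p.plasma_samples if s.visit == landmark_visit),
                 None)
        days[p.patient_id] = s.collection_day if s is not None else np.nan
    return pd.Series(days, name="landmark_day")


def survival_records(cohort: Sequence[SyntheticPatient]) -> pd.DataFrame:
    return pd.DataFrame(
        {p.patient_id: {"os_time": p.survival.os_time,
                        "os_event": p.survival.os_event,
                        "pfs_time": p.survival.pfs_time,
                        "pfs_event": p.survival.pfs_event}
         for p in cohort}).T


def train_model(matrix: FeatureMatrix, data, recist: pd.Series,
                enet: ElasticNetConfig,
                durable_horizon_days: float = 1095.0,
                run_loocv: bool = True,
                fallback_features: Sequence[str] = (),
                ) -> tuple[FinalModel, dict]:
    """LOOCV feature selection, final fit and threshold choice.

    When the retention+gain rule selects nothing (degenerate small runs),
    falls back to the highest-retention features, then to
    ``fallback_features``.  The mPD threshold falls back to a pooled
    optimal split when a week-6 subgroup is too small.
    """
    report: dict = {}
    selected: list[str] = []
    if run_loocv:
        loocv = loocv_elastic_net(matrix, data, enet)
        importances = rank_features(loocv)
        selected = top_features(importances, enet.retention_threshold)
        report["loocv_cindex"] = loocv.cindex
        report["importances"] = importances
        if not selected:
            retained = [fi.name for fi in importances
                        if fi.retention >= enet.retention_threshold]
            selected = retained[:5]
    if not selected:
        selected = list(fallback_features)
    if not selected:
        raise ValueError("no features selected and no fallback provided")
    report["features"] = selected

    model = fit_final_model(matrix, data, selected,
                            metadata={"endpoint": data.endpoint})
    ids = [pid for pid in data.frame.index if pid in matrix.values.index]
    preds = model.score(matrix.values.loc[ids])
    try:
        mpd = select_mpd_threshold(preds, recist, data)
    except SubgroupSizeError as exc:
        warnings.warn(f"{exc}; using pooled optimal split for mPD")
        from .survival import _optimal_logrank_split

        mpd = _optimal_logrank_split(
            preds, data.frame.loc[ids, "time"].to_numpy(dtype=float),
            data.frame.loc[ids, "event"].to_numpy(dtype=bool), (0.1, 0.9))
    mresp = select_mresp_threshold(preds, data, durable_horizon_days)
    if mresp >= mpd:  # degenerate ordering on tiny runs
        warnings.warn("mResp threshold not below mPD threshold; "
                      "nudging mResp to keep bins ordered")
        mresp = mpd - 1e-9
    model.mpd_threshold = float(mpd)
    model.mresp_threshold = float(mresp)
    report["predictions"] = preds
    return model, report


def run_all(config: PipelineConfig) -> dict:
    """Execute the full chain and write all artifacts under ``outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = config.meta()

    log.info("stage=simulate seed=%s", config.seed)
    cohort_cfg = CohortConfig(**{"seed": config.seed, **config.cohort})
    cohort = generate_cohort(cohort_cfg)
    write_cohort(cohort, outdir / "cohort", metadata=meta)

    log.info("stage=process n_patients=%d", len(cohort))
    panel = synthetic_normal_panel(config.seed, config.panel_size)
    processed = process_cohort(cohort, panel)
    _write_processed(processed, outdir, meta)

    log.info("stage=features landmark=%s", config.landmark_visit)
    catalog = default_catalog()
    matrix = assemble_feature_matrix(
        processed, config.landmark_visit, catalog,
        include_clinical=config.include_clinical,
        visit_days=cohort_cfg.visit_days)
    io.write_table(matrix.values.reset_index(), outdir / "features.csv",
                   meta, sep=",")

    split = split_cohort(processed, config.train_fraction, config.seed)
    io.write_table(split.rename_axis("patient_id").reset_index(),
                   outdir / "split.tsv", meta)

    records = survival_records(processed)
    lmk_days = landmark_days_for(processed, config.landmark_visit)
    recist = recist_series(processed)

    train_ids = split[split == "train"].index
    data_train = landmark_rebaseline(
        records.loc[records.index.intersection(train_ids)],
        lmk_days, config.endpoint)
    train_matrix = FeatureMatrix(
        values=matrix.values.loc[matrix.values.index.intersection(train_ids)],
        mask=matrix.mask.loc[matrix.mask.index.intersection(train_ids)])

    log.info("stage=train n_at_risk=%d", len(data_train.frame))
    enet = ElasticNetConfig(**{"seed": config.seed, **config.elastic_net})
    model, report = train_model(
        train_matrix, data_train, recist, enet,
        durable_horizon_days=config.durable_horizon_days,
        fallback_features=[f"{config.landmark_visit}:log10_mtm"])
    io.write_json(model.to_dict(), outdir / "model.json", meta)
    preds = report["predictions"]
    calls_train = call_molecular_response(preds.to_numpy(), model)
    io.write_table(
        pd.DataFrame({"patient_id": preds.index, "score": preds.to_numpy(),
                      "call": calls_train}),
        outdir / "predictions.csv", meta, sep=",")

    log.info("stage=evaluate")
    test_ids = split[split == "test"].index
    data_test = landmark_rebaseline(
        records.loc[records.index.intersection(test_ids)],
        lmk_days, config.endpoint)
    eval_ids = [pid for pid in data_test.frame.index
                if pid in matrix.values.index]
    summary: dict = {"train_cindex": model.train_cindex.estimate
                     if model.train_cindex else None}
    if "loocv_cindex" in report:
        summary["loocv_cindex"] = report["loocv_cindex"].estimate
    calls = pd.Series(index=pd.Index([], dtype=object), dtype=object)
    if eval_ids:
        scores_test = model.score(matrix.values.loc[eval_ids])
        calls = pd.Series(
            call_molecular_response(scores_test.to_numpy(), model),
            index=scores_test.index)
        tt = data_test.frame.loc[eval_ids]
        cix = concordance_index(scores_test.to_numpy(),
                                tt["time"].to_numpy(),
                                tt["event"].to_numpy(dtype=bool))
        summary["test_cindex"] = cix.estimate
        summary["test_cindex_se"] = cix.se
        high = (calls == "mPD").to_numpy()
        if 0 < high.sum() < len(high):
            try:
                summary["test_mpd_vs_rest"] = km_cox_summary(
                    tt["time"].to_numpy(), tt["event"].to_numpy(dtype=bool),
                    np.where(high, "mPD", "mSD+mResp"))
            except ValueError as exc:
                summary["test_mpd_vs_rest"] = f"not estimable: {exc}"
    io.write_json(summary, outdir / "summary.json", meta)

    log.info("stage=trial-sim")
    ts_cfg = TrialSimConfig(**{"seed": config.seed, **config.trial_sim})
    test_patients = [p for p in processed if p.patient_id in set(test_ids)]
    table = make_endpoint_table(test_patients, calls)
    control = cohort_cfg.arm_labels[0]
    go_frames = []
    for active in cohort_cfg.arm_labels[1:]:
        gr = run_operating_characteristics(table, active, control, ts_cfg)
        gr.insert(0, "active_arm", active)
        go_frames.append(gr)
    go_rates = pd.concat(go_frames, ignore_index=True)
    io.write_table(go_rates, outdir / "go_rates.csv", meta, sep=",")

    return {"model": model, "summary": summary, "go_rates": go_rates,
            "split": split, "matrix": matrix}


def _write_processed(processed: Sequence[SyntheticPatient], outdir: Path,
                     meta: Mapping) -> None:
    var_rows, samp_rows = [], []
    for p in processed:
        for s in p.plasma_samples:
            samp_rows.append({
                "patient_id": p.patient_id, "visit": s.visit,
                "collection_day": s.collection_day,
                "cfdna_conc": s.cfdna_conc, "qc_pass": int(s.qc_pass),
                "mtm": s.mtm if s.mtm is not None else "",
            })
            for o in s.observations:
                var_rows.append({
                    "patient_id": p.patient_id, "visit": s.visit,
                    "variant_id": o.variant_id, "gene": o.gene,
                    "pathogenic": int(o.pathogenic),
                    "nrv": o.read_support.nrv, "nrr": o.read_support.nrr,
                    "nre": o.read_support.nre,
                    "vaf": o.vaf, "censored_af": o.censored_af,
                    "classification": o.classification,
                    "pbmc_positive": int(o.pbmc_positive),
                })
    io.write_table(pd.DataFrame(var_rows),
                   outdir / "processed_variants.tsv", meta)
    io.write_table(pd.DataFrame(samp_rows), outdir / "samples_mtm.tsv", meta)
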