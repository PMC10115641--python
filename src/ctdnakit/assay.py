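"""Read-count post-processing for longitudinal plasma variant panels.

Converts raw per-variant read counts into variant allele fractions (VAF),
classifies calls against a presumed-normal background panel, censors
sub-quantitation allele fractions, removes germline/CHIP variants using
matched PBMC calls, and summarizes per-sample ctDNA burden as mean tumor
molecules per mL plasma (MTM).

The VAF of a tracked variant is estimated from consensus reads that either
support the variant (NRv) or the reference (NRr); equivocal reads (NRe)
carry no discriminating value and are excluded from both numerator and
denominator.  A call is *positive* when it has at least a minimum number of
variant-supporting reads and a VAF above the maximum VAF seen at that site
in presumed-normal samples; *negative* when the VAF falls below the 0.95
quantile of the normal background; *equivocal* otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "ConfigurationError",
    "ReadSupport",
    "AssayLimits",
    "PresumedNormalPanel",
    "VariantObservation",
    "PlasmaSample",
    "estimate_vaf",
    "classify_variant",
    "censor_af",
    "subtract_pbmc",
    "compute_mtm",
    "process_sample",
    "CHIP_GENE_BLOCKLIST",
    "MASS_PER_GENOME_PG",
]

#: Canonical CHIP-prone genes excluded from panel designs; available as an
#: optional gene blocklist when PBMC subtraction alone is not desired.
CHIP_GENE_BLOCKLIST = (
    "TET2", "DNMT3A", "CBL", "PPM1D", "CHEK2", "JAK2", "ASXL1", "SF3B1",
)

#: Mass of one haploid human genome in picograms, used to convert cfDNA
#: concentration (ng/mL) into genome equivalents per mL.
MASS_PER_GENOME_PG = 3.3

VISIT_LABELS = ("BL", "C2D1", "C3D1", "C4D1", "C8D1")


class ConfigurationError(ValueError):
    """Invalid assay or panel configuration."""


@dataclass(frozen=True)
class ReadSupport:
    """Consensus-read counts at one tracked variant locus.

    nrv: reads supporting the presence of the variant.
    nrr: reads supporting the reference (absence of the variant).
    nre: reads with no discriminating value (ignored in VAF estimation).
    """

    nrv: int
    nrr: int
    nre: int = 0

    def __post_init__(self) -> None:
        for name in ("nrv", "nrr", "nre"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")


@dataclass(frozen=True)
class AssayLimits:
    """Limit of detection and lower limit of quantitation, as allele fractions."""

    lod: float = 0.001
    loq: float = 0.005

    def __post_init__(self) -> None:
        if not (0.0 < self.lod < self.loq < 1.0):
            raise ConfigurationError(
                f"require 0 < lod < loq < 1, got lod={self.lod}, loq={self.loq}"
            )


class PresumedNormalPanel:
    """Background VAF distribution from presumed-normal plasma samples.

    Supports a pooled (variant-agnostic) background and, optionally,
    per-variant backgrounds; per-variant values take precedence when present.
    Quantiles use linear interpolation between order statistics.
    """

    def __init__(
        self,
        pooled: Sequence[float] | np.ndarray,
        per_variant: Mapping[str, Sequence[float]] | None = None,
        min_supporting_reads: int = 2,
    ) -> None:
        pooled = np.asarray(pooled, dtype=float)
        if pooled.size == 0:
            raise ConfigurationError("presumed-normal panel must be non-empty")
        if pooled.min() < 0 or pooled.max() > 1:
            raise ConfigurationError("panel VAFs must lie in [0, 1]")
        if min_supporting_reads < 0:
            raise ConfigurationError("min_supporting_reads must be >= 0")
        self.pooled = pooled
        self.per_variant = {
            k: np.asarray(v, dtype=float) for k, v in (per_variant or {}).items()
        }
        for vid, arr in self.per_variant.items():
            if arr.size == 0:
                raise ConfigurationError(f"empty per-variant panel for {vid!r}")
        self.min_supporting_reads = int(min_supporting_reads)

    def _values(self, variant_id: str | None) -> np.ndarray:
        if variant_id is not None and variant_id in self.per_variant:
            return self.per_variant[variant_id]
        return self.pooled

    def max_vaf(self, variant_id: str | None = None) -> float:
        return float(self._values(variant_id).max())

    def quantile95(self, variant_id: str | None = None) -> float:
        return float(np.quantile(self._values(variant_id), 0.95))


@dataclass
class VariantObservation:
    """One tracked variant measured in one plasma sample."""

    variant_id: str
    gene: str
    pathogenic: bool
    visit: str
    read_support: ReadSupport
    vaf: float | None = None
    censored_af: float | None = None
    classification: str | None = None
    pbmc_positive: bool = False


@dataclass
class PlasmaSample:
    """One patient-visit plasma collection with its variant observations."""

    patient_id: str
    visit: str
    collection_day: float
    cfdna_conc: float
    observations: list[VariantObservation] = field(default_factory=list)
    qc_pass: bool = True
    mtm: float | None = None

    def somatic_observations(self) -> list[VariantObservation]:
        """Observations surviving PBMC subtraction (the analysis channel)."""
        return [o for o in self.observations if not o.pbmc_positive]

    def positive_somatic(self) -> list[VariantObservation]:
        return [
            o for o in self.somatic_observations() if o.classification == "positive"
        ]


def estimate_vaf(rs: ReadSupport) -> float:
    """VAF = NRv / (NRv + NRr); equivocal reads are ignored.

    Returns ``nan`` when no informative reads are available (degenerate
    denominator) — deliberately distinct from a measured zero.
    """
    denom = rs.nrv + rs.nrr
    if denom == 0:
        return float("nan")
    return rs.nrv / denom


def classify_variant(
    vaf: float,
    nrv: int,
    panel: PresumedNormalPanel,
    variant_id: str | None = None,
) -> str:
    """Classify a call as positive / negative / equivocal against the panel.

    Positive: at least ``panel.min_supporting_reads`` variant-supporting
    reads and VAF strictly above the panel maximum.  Negative: VAF strictly
    below the panel's 0.95 quantile.  Equivocal otherwise.  When a
    degenerate panel makes both rules fire, positive takes precedence (it is
    the stricter, read-count-backed condition).
    """
    if vaf is None or math.isnan(vaf):
        return "equivocal"
    if nrv >= panel.min_supporting_reads and vaf > panel.max_vaf(variant_id):
        return "positive"
    if vaf < panel.quantile95(variant_id):
        return "negative"
    return "equivocal"


def censor_af(af: float, limits: AssayLimits | None = None) -> float:
    """Censor sub-quantitation allele fractions.

    AF at or above the LOQ is reported unchanged; AF in [LOD, LOQ) is
    censored to LOQ/2; AF in (0, LOD) is censored to LOQ/4.  An AF of
    exactly zero means the variant was not reported and carries no AF, so it
    stays zero.
    """
    if limits is None:
        limits = AssayLimits()
    if math.isnan(af):
        return float("nan")
    if not (0.0 <= af <= 1.0):
        raise ValueError(f"allele fraction must lie in [0, 1], got {af}")
    if af >= limits.loq or af == 0.0:
        return af
    if af >= limits.lod:
        return limits.loq / 2.0
    return limits.loq / 4.0


def subtract_pbmc(
    plasma_obs: Iterable[VariantObservation],
    pbmc_positive_ids: set[str] | frozenset[str],
) -> tuple[list[VariantObservation], list[VariantObservation]]:
    """Remove variants called positive in matched PBMCs (germline/CHIP).

    Returns ``(kept, removed)``: the somatic channel and an audit channel in
    which removed observations carry ``pbmc_positive=True``.  Idempotent:
    applying it to the kept channel again removes nothing.
    """
    kept: list[VariantObservation] = []
    removed: list[VariantObservation] = []
    for o in plasma_obs:
        if o.variant_id in pbmc_positive_ids:
            removed.append(replace(o, pbmc_positive=True))
        else:
            kept.append(o)
    return kept, removed


def compute_mtm(
    sample: PlasmaSample,
    mass_per_genome_pg: float = MASS_PER_GENOME_PG,
    somatic_only: bool = True,
) -> float:
    """Mean tumor molecules per mL plasma.

    MTM = (mean censored AF over positive observations) x (cfDNA haploid
    genome equivalents per mL), where genome equivalents derive from the
    cfDNA concentration in ng/mL and the haploid genome mass in pg.  With
    ``somatic_only`` (the default), PBMC-positive observations are excluded.
    Returns 0 when no positive observation remains.
    """
    if sample.cfdna_conc < 0:
        raise ValueError(f"negative cfDNA concentration: {sample.cfdna_conc}")
    obs = sample.positive_somatic() if somatic_only else [
        o for o in sample.observations if o.classification == "positive"
    ]
    afs = [o.censored_af for o in obs if o.censored_af is not None]
    if not afs:
        return 0.0
    mean_af = float(np.mean(afs))
    genome_equiv_per_ml = sample.cfdna_conc / (mass_per_genome_pg * 1e-3)
    return mean_af * genome_equiv_per_ml


def process_sample(
    sample: PlasmaSample,
    panel: PresumedNormalPanel,
    limits: AssayLimits | None = None,
    pbmc_positive_ids: set[str] | frozenset[str] = frozenset(),
    mass_per_genome_pg: float = MASS_PER_GENOME_PG,
    gene_blocklist: Sequence[str] = (),
) -> PlasmaSample:
    """Run the full per-sample post-processing chain.

    Estimates VAF, classifies against the normal panel, censors
    sub-quantitation AFs, subtracts PBMC-positive (and optionally
    blocklisted-gene) variants, and computes MTM.  QC-failed samples keep
    their collection record but carry no variant data and no MTM.
    """
    if limits is None:
        limits = AssayLimits()
    if not sample.qc_pass:
        return replace(sample, observations=[], mtm=None)
    blocked = set(gene_blocklist)
    processed: list[VariantObservation] = []
    for o in sample.observations:
        vaf = estimate_vaf(o.read_support)
        cls = classify_variant(vaf, o.read_support.nrv, panel, o.variant_id)
        caf = censor_af(vaf, limits) if not math.isnan(vaf) else float("nan")
        processed.append(
            replace(o, vaf=vaf, censored_af=caf, classification=cls)
        )
    pbmc_like = set(pbmc_positive_ids) | {
        o.variant_id for o in processed if o.gene in blocked
    }
    kept, removed = subtract_pbmc(processed, pbmc_like)
    out = replace(sample, observations=kept + removed)
    out.mtm = compute_mtm(out, mass_per_genome_pg=mass_per_genome_pg)
    return out
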