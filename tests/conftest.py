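import pytest

import ctdnakit as ck
from ctdnakit.pipeline import process_cohort, synthetic_normal_panel


def make_sample(afs, cfdna=10.0, visit="BL", patient="PX", qc_pass=True,
                day=None, pathogenic=None):
    """Processed plasma sample with given positive somatic censored AFs."""
    day = day if day is not None else {"BL": 0, "C2D1": 21, "C3D1": 42,
                                       "C4D1": 63, "C8D1": 147}[visit]
    obs = []
    for k, af in enumerate(afs):
        obs.append(ck.VariantObservation(
            variant_id=f"{patient}:G:{k}", gene="TP53",
            pathogenic=(pathogenic[k] if pathogenic else True), visit=visit,
            read_support=ck.ReadSupport(int(af * 1000), 1000),
            vaf=af, censored_af=af, classification="positive"))
    s = ck.PlasmaSample(patient, visit, float(day), cfdna, obs,
                        qc_pass=qc_pass)
    s.mtm = ck.compute_mtm(s) if qc_pass else None
    return s


@pytest.fixture(scope="session")
def small_cohort():
    return ck.generate_cohort(ck.CohortConfig(n_patients=80, seed=5))


@pytest.fixture(scope="session")
def processed_cohort(small_cohort):
    return process_cohort(small_cohort, synthetic_normal_panel(5))


@pytest.fixture(scope="session")
def catalog():
    return ck.default_catalog()
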