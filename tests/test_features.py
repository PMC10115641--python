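import math

import numpy as np
import pandas as pd
import pytest

import ctdnakit as ck
from ctdnakit.features import AllMissingError, impute_fit

from conftest import make_sample


class TestLevelMetrics:
    def test_af_summaries(self, catalog):
        s = make_sample([0.02, 0.01, 0.03])
        vals = ck.derive_level_metrics(s, catalog)
        assert vals["mean_af"] == pytest.approx(0.02)
        assert vals["max_af"] == pytest.approx(0.03)
        assert vals["n_mut"] == 3

    def test_negative_sample_yields_zero_burden(self, catalog):
        s = make_sample([])
        vals = ck.derive_level_metrics(s, catalog)
        assert vals["mtm"] == 0.0
        assert vals["detected"] == 0.0
        assert vals["n_mut"] == 0.0

    def test_qc_failed_sample_is_missing_not_zero(self, catalog):
        s = make_sample([0.02], qc_pass=False)
        vals = ck.derive_level_metrics(s, catalog)
        assert all(math.isnan(v) for v in vals.values())


class TestChangeMetrics:
    def test_percent_change(self, catalog):
        # MTM 64 -> 19.2 is a 70% reduction
        bl = make_sample([0.0128], cfdna=16.5, visit="BL")
        assert bl.mtm == pytest.approx(64.0)
        tx = make_sample([0.00384], cfdna=16.5, visit="C3D1")
        assert tx.mtm == pytest.approx(19.2)
        vals = ck.derive_change_metrics(bl, tx, [bl, tx], catalog)
        assert vals["pct_mtm"] == pytest.approx(-70.0)

    def test_clearance_below_one_mtm(self, catalog):
        bl = make_sample([0.01])
        tx = make_sample([0.0001], cfdna=10.0, visit="C3D1")
        assert tx.mtm < 1.0
        vals = ck.derive_change_metrics(bl, tx, [bl, tx], catalog)
        assert vals["clearance"] == 1.0

    def test_zero_baseline_ratio_missing_absolute_kept(self, catalog):
        bl = make_sample([])
        tx = make_sample([0.00165], cfdna=10.0, visit="C3D1")  # 5 MTM
        vals = ck.derive_change_metrics(bl, tx, [bl, tx], catalog)
        assert math.isnan(vals["pct_mtm"])
        assert vals["abs_mtm"] == pytest.approx(5.0)

    def test_scale_invariance_of_percent_change(self, catalog):
        bl, tx = make_sample([0.01, 0.02]), make_sample([0.005, 0.01],
                                                        visit="C3D1")
        v1 = ck.derive_change_metrics(bl, tx, [bl, tx], catalog)
        k = 3.7
        bl2 = make_sample([0.01 * k, 0.02 * k], cfdna=10.0 * k)
        tx2 = make_sample([0.005 * k, 0.01 * k], cfdna=10.0 * k,
                          visit="C3D1")
        v2 = ck.derive_change_metrics(bl2, tx2, [bl2, tx2], catalog)
        assert v1["pct_mean_af"] == pytest.approx(v2["pct_mean_af"])
        assert v1["pct_mtm"] == pytest.approx(v2["pct_mtm"])

    def test_auc_is_time_weighted_mean(self, catalog):
        bl = make_sample([0.0033], cfdna=10.0)          # 10 MTM at day 0
        c2 = make_sample([0.00165], cfdna=10.0, visit="C2D1")   # 5 MTM day 21
        c3 = make_sample([0.00165], cfdna=10.0, visit="C3D1")   # 5 MTM day 42
        vals = ck.derive_change_metrics(bl, c3, [bl, c2, c3], catalog)
        # trapezoid: (7.5*21 + 5*21)/42 = 6.25
        assert vals["auc_mtm"] == pytest.approx(6.25)


def _dummy_patient(pid, samples, covs=None, assessments=None):
    from ctdnakit.cohort import SurvivalRecord, SyntheticPatient

    return SyntheticPatient(
        patient_id=pid, arm="BCP", latent_class="SD", enrollment_day=0,
        baseline_covariates=covs or {"age": 60, "sex": "M", "ecog": 0,
                                     "smoker": "y", "n_met_sites": 2,
                                     "pdl1_high": 0, "baseline_sld": 70.0},
        plasma_samples=samples, pbmc_calls=[],
        survival=SurvivalRecord(500.0, True, 300.0, True),
        tumor_assessments=assessments or [])


class TestAssembleMatrix:
    def test_column_count_is_catalog_arithmetic(self):
        """landmark C3D1 with L level and C change metrics gives
        3L + 2C ctDNA columns, independent of data content."""
        L, C = 19, 59
        catalog = ck.MetricCatalog(
            level={f"lv{i}": (lambda s: 1.0) for i in range(L)},
            change={f"ch{i}": (lambda b, t, h: 1.0) for i in range(C)})
        pats = [_dummy_patient("P1", [make_sample([0.01], patient="P1"),
                                      make_sample([0.01], visit="C2D1",
                                                  patient="P1"),
                                      make_sample([0.01], visit="C3D1",
                                                  patient="P1")])]
        m = ck.assemble_feature_matrix(pats, "C3D1", catalog)
        assert m.values.shape == (1, 3 * L + 2 * C)

    def test_landmark_bl_gives_level_metrics_only(self, catalog):
        pats = [_dummy_patient("P1", [make_sample([0.01], patient="P1")])]
        m = ck.assemble_feature_matrix(pats, "BL", catalog)
        assert m.values.shape == (1, len(catalog.level))
        assert all(c.startswith("BL:") for c in m.feature_names)

    def test_row_requires_landmark_collection_record(self, catalog):
        pats = [
            _dummy_patient("HAS", [make_sample([0.01], patient="HAS"),
                                   make_sample([0.01], visit="C3D1",
                                               patient="HAS")]),
            _dummy_patient("LACKS", [make_sample([0.01], patient="LACKS")]),
        ]
        m = ck.assemble_feature_matrix(pats, "C3D1", catalog)
        assert m.patient_ids == ["HAS"]

    def test_qc_failed_landmark_row_present_cells_missing(self, catalog):
        pats = [_dummy_patient("P1", [
            make_sample([0.01], patient="P1"),
            make_sample([0.01], visit="C3D1", patient="P1", qc_pass=False)])]
        m = ck.assemble_feature_matrix(pats, "C3D1", catalog)
        assert m.patient_ids == ["P1"]
        assert m.values.loc["P1", "C3D1:mtm"] != m.values.loc["P1", "C3D1:mtm"]
        assert not math.isnan(m.values.loc["P1", "BL:mtm"])

    def test_unknown_landmark_rejected(self, catalog):
        with pytest.raises(ValueError, match="C9D9"):
            ck.assemble_feature_matrix([], "C9D9", catalog)

    def test_clinical_columns_for_c3d1(self, catalog):
        from ctdnakit.cohort import TumorAssessment

        pats = [_dummy_patient(
            "P1",
            [make_sample([0.01], patient="P1"),
             make_sample([0.01], visit="C3D1", patient="P1")],
            assessments=[TumorAssessment(0, 70.0, None),
                         TumorAssessment(6, 49.0, "PR")])]
        m = ck.assemble_feature_matrix(pats, "C3D1", catalog,
                                       include_clinical=True)
        assert m.values.loc["P1", "clin:sld_pct_change"] == pytest.approx(-30)
        assert m.values.loc["P1", "clin:age"] == 60


def _matrix(df):
    return ck.FeatureMatrix(values=df, mask=df.isna())


class TestImputation:
    def test_median_fill(self):
        df = pd.DataFrame({"a": [1.0, 2.0, np.nan, 4.0]},
                          index=list("wxyz"))
        out = ck.impute_missing(_matrix(df))
        assert out.values.loc["y", "a"] == 2.0   # median of {1,2,4}

    def test_no_missing_is_identity(self):
        df = pd.DataFrame({"a": [1.0, 2.0]}, index=["x", "y"])
        out = ck.impute_missing(_matrix(df))
        pd.testing.assert_frame_equal(out.values, df)

    def test_all_missing_column_errors_with_names(self):
        df = pd.DataFrame({"bad": [np.nan, np.nan], "ok": [1.0, 2.0]},
                          index=["x", "y"])
        with pytest.raises(AllMissingError, match="bad"):
            impute_fit(_matrix(df))

    def test_frozen_medians_applied_to_test(self):
        train = pd.DataFrame({"a": [0.0, 10.0, 20.0]}, index=list("abc"))
        med = impute_fit(_matrix(train))
        test = pd.DataFrame({"a": [np.nan]}, index=["t"])
        out = ck.impute_missing(_matrix(test), medians=med)
        assert out.values.loc["t", "a"] == 10.0

    def test_observed_cells_bit_identical(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.standard_normal((20, 3)),
                          columns=list("abc"))
        df.iloc[3, 1] = np.nan
        out = ck.impute_missing(_matrix(df))
        mask = (~df.isna()).to_numpy()
        assert (out.values.to_numpy()[mask] == df.to_numpy()[mask]).all()


class TestIqrScaling:
    def test_linear_interpolation_quartiles(self):
        df = pd.DataFrame({"a": np.arange(101, dtype=float)})
        scalers = ck.iqr_fit(_matrix(df))
        assert scalers["iqr"]["a"] == pytest.approx(50.0)
        out = ck.iqr_apply(_matrix(df), scalers)
        assert out.values["a"].iloc[100] == pytest.approx(2.0)

    def test_scaled_train_iqr_is_one(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.standard_normal((50, 4)),
                          columns=list("abcd"))
        scalers = ck.iqr_fit(_matrix(df))
        out = ck.iqr_apply(_matrix(df), scalers)
        iqr = out.values.quantile(0.75) - out.values.quantile(0.25)
        assert np.allclose(iqr, 1.0)

    def test_constant_feature_passes_through_with_warning(self):
        df = pd.DataFrame({"c": [5.0, 5.0, 5.0]})
        with pytest.warns(UserWarning, match="constant"):
            scalers = ck.iqr_fit(_matrix(df))
        out = ck.iqr_apply(_matrix(df), scalers)
        assert (out.values["c"] == 5.0).all()
        assert scalers["constant"] == ["c"]

    def test_train_scalers_applied_to_test(self):
        train = pd.DataFrame({"a": np.arange(101, dtype=float)})
        test = pd.DataFrame({"a": [10.0]})
        scalers = ck.iqr_fit(_matrix(train))
        out = ck.iqr_apply(_matrix(test), scalers)
        assert out.values["a"].iloc[0] == pytest.approx(10.0 / 50.0)
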