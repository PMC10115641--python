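import numpy as np
import pandas as pd
import pytest

import ctdnakit as ck
from ctdnakit.cohort import simulate_survival_features
from ctdnakit.features import FeatureMatrix
from ctdnakit.survival import (
    FoldResult,
    LoocvResult,
    SubgroupSizeError,
    _run_fold,
    breslow_loglik,
)


def _records(times, events):
    ids = [f"P{i}" for i in range(len(times))]
    return pd.DataFrame({"os_time": times, "os_event": events,
                         "pfs_time": times, "pfs_event": events}, index=ids)


class TestLandmarkRebaseline:
    def test_event_before_landmark_excluded(self):
        rec = _records([30.0], [True])
        data = ck.landmark_rebaseline(rec, pd.Series({"P0": 42.0}), "os")
        assert len(data.frame) == 0
        assert data.excluded.iloc[0]["reason"] == "event before landmark"

    def test_censored_after_landmark_rebaselined(self):
        rec = _records([400.0], [False])
        data = ck.landmark_rebaseline(rec, pd.Series({"P0": 42.0}), "os")
        assert data.frame.loc["P0", "time"] == pytest.approx(358.0)
        assert not data.frame.loc["P0", "event"]

    def test_event_exactly_at_landmark_excluded(self):
        rec = _records([42.0], [True])
        data = ck.landmark_rebaseline(rec, pd.Series({"P0": 42.0}), "os")
        assert len(data.frame) == 0

    def test_missing_collection_day(self):
        rec = _records([400.0], [True])
        data = ck.landmark_rebaseline(rec, pd.Series(dtype=float), "os")
        assert data.excluded.iloc[0]["reason"] == "no collection"

    def test_rebaselined_times_strictly_positive(self):
        rng = np.random.default_rng(0)
        rec = _records(rng.exponential(100, 50), rng.random(50) < 0.7)
        days = pd.Series(42.0, index=rec.index)
        data = ck.landmark_rebaseline(rec, days, "os")
        assert (data.frame["time"] > 0).all()
        # landmarking removes immortal time: every at-risk patient shares
        # the "survived to landmark" property, so it carries no contrast
        assert (rec.loc[data.frame.index, "os_time"] > 42.0).all()


class TestBreslowLoglik:
    def test_matches_lifelines_on_continuous_times(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(1)
        n = 60
        x = rng.standard_normal((n, 2))
        t = rng.exponential(10, n)
        e = rng.random(n) < 0.7
        df = pd.DataFrame(x, columns=["a", "b"])
        df["t"], df["e"] = t, e.astype(int)
        cph = CoxPHFitter()
        cph.fit(df, "t", "e")
        beta = cph.params_.to_numpy()
        # no ties in continuous times: Breslow equals Efron equals exact
        ll = breslow_loglik(x @ beta, t, e)
        assert ll[0] == pytest.approx(cph.log_likelihood_)

    def test_vectorized_over_columns(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(10, 20)
        e = rng.random(20) < 0.7
        lp = rng.standard_normal((20, 4))
        ll = breslow_loglik(lp, t, e)
        singles = [breslow_loglik(lp[:, j], t, e)[0] for j in range(4)]
        assert np.allclose(ll, singles)


def _null_setup(n=40, p=3, seed=0):
    X, rec = simulate_survival_features(n, p, None, censoring=0.3, seed=seed)
    data = ck.landmark_rebaseline(rec, pd.Series(0.0, index=X.index), "os")
    return FeatureMatrix(values=X, mask=X.isna()), data


class TestLoocvElasticNet:
    def test_sample_size_guard(self):
        m, data = _null_setup(n=10)
        with pytest.raises(ValueError, match="at-risk"):
            ck.loocv_elastic_net(m, data, ck.ElasticNetConfig())

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ck.ElasticNetConfig(alpha=0.0)
        with pytest.raises(ValueError):
            ck.ElasticNetConfig(nested_repeats=0)

    def test_all_constant_features_give_tie_cindex(self):
        m, data = _null_setup(n=30)
        const = FeatureMatrix(
            values=pd.DataFrame(1.0, index=m.values.index,
                                columns=["c1", "c2"]),
            mask=pd.DataFrame(False, index=m.values.index,
                              columns=["c1", "c2"]))
        res = ck.loocv_elastic_net(const, data,
                                   ck.ElasticNetConfig(nested_repeats=1))
        assert all(f.selected == () for f in res.folds)
        assert (res.predictions == 0.0).all()
        assert res.cindex.estimate == 0.5

    def test_no_leakage_from_held_out_patient(self):
        """Perturbing the held-out patient's features never changes the
        fold's imputation medians, scalers, lambda or selection."""
        m, data = _null_setup(n=30, p=4, seed=3)
        cfg = ck.ElasticNetConfig(nested_repeats=2, inner_folds=3, seed=0)
        ids = list(data.frame.index)
        time = data.frame["time"].to_numpy(float)
        event = data.frame["event"].to_numpy(bool)
        tr = np.ones(len(ids), bool)
        tr[0] = False
        cols = list(m.values.columns)
        f1 = _run_fold(m.values, time, event, tr, 0, ids[0], cols, cfg)
        perturbed = m.values.copy()
        perturbed.iloc[0] = perturbed.iloc[0] + 1000.0
        f2 = _run_fold(perturbed, time, event, tr, 0, ids[0], cols, cfg)
        assert f1.lam == f2.lam
        assert f1.selected == f2.selected
        if f1.selected:
            assert f1.prediction != f2.prediction

    def test_informative_feature_found(self):
        """A strong feature is retained in most folds and lifts the pooled
        c-index (small-n sanity version of the recovery experiment)."""
        X, rec = simulate_survival_features(60, 4, {0: 1.5},
                                            censoring=0.2, seed=8)
        data = ck.landmark_rebaseline(rec, pd.Series(0.0, index=X.index),
                                      "os")
        m = FeatureMatrix(values=X, mask=X.isna())
        res = ck.loocv_elastic_net(
            m, data, ck.ElasticNetConfig(nested_repeats=3, inner_folds=3,
                                         seed=1))
        imps = {f.name: f for f in ck.rank_features(res)}
        assert imps["f0"].retention >= 0.5
        assert res.cindex.estimate > 0.55


class TestRankFeatures:
    def test_retention_and_gain_arithmetic(self):
        folds = [FoldResult("a", 0.1, ("x",), 0.0, {"x": 1.0}),
                 FoldResult("b", 0.1, ("x", "y"), 0.0,
                            {"x": 3.0, "y": -1.0}),
                 FoldResult("c", 0.1, (), 0.0, {})]
        res = LoocvResult(folds=folds, predictions=pd.Series(dtype=float),
                          cindex=None, feature_names=("x", "y", "z"),
                          config=ck.ElasticNetConfig())
        imps = {f.name: f for f in ck.rank_features(res)}
        assert imps["x"].retention == pytest.approx(2 / 3)
        assert imps["x"].gain == pytest.approx(2.0)
        assert imps["y"].retention == pytest.approx(1 / 3)
        assert imps["z"].retention == 0.0 and imps["z"].gain is None
        assert ck.top_features(list(imps.values())) == ["x"]


class TestFinalModel:
    def test_single_feature_score_is_monotone(self):
        X, rec = simulate_survival_features(80, 3, {0: 1.0}, seed=2)
        data = ck.landmark_rebaseline(rec, pd.Series(0.0, index=X.index),
                                      "os")
        m = FeatureMatrix(values=X, mask=X.isna())
        model = ck.fit_final_model(m, data, ["f0"])
        scores = model.score(X)
        order = X["f0"].argsort().to_numpy()
        signed = scores.to_numpy()[order] * np.sign(model.coefficients[0])
        assert (np.diff(signed) >= 0).all()
        assert model.train_cindex.estimate >= 0.5

    def test_recovers_generative_sign(self):
        X, rec = simulate_survival_features(200, 5, {2: 1.0}, seed=4)
        data = ck.landmark_rebaseline(rec, pd.Series(0.0, index=X.index),
                                      "os")
        m = FeatureMatrix(values=X, mask=X.isna())
        model = ck.fit_final_model(m, data, ["f2", "f0"])
        assert model.coefficients[0] > 0   # higher risk for higher f2

    def test_empty_feature_list_rejected(self):
        m, data = _null_setup(n=30)
        with pytest.raises(ValueError):
            ck.fit_final_model(m, data, [])

    def test_round_trips_through_dict(self):
        X, rec = simulate_survival_features(50, 2, {0: 1.0}, seed=5)
        data = ck.landmark_rebaseline(rec, pd.Series(0.0, index=X.index),
                                      "os")
        m = FeatureMatrix(values=X, mask=X.isna())
        model = ck.fit_final_model(m, data, ["f0"])
        model.mpd_threshold, model.mresp_threshold = 0.3, 0.05
        clone = ck.FinalModel.from_dict(model.to_dict())
        pd.testing.assert_series_equal(model.score(X), clone.score(X))


def _threshold_setup(n_per_group=30, sep=0.5, seed=0):
    """Two week-6 subgroups whose scores perfectly separate short and long
    survivors at `sep`."""
    rng = np.random.default_rng(seed)
    rows, recist, preds = {}, {}, {}
    k = 0
    for sub in ("SD", "PR"):
        for i in range(n_per_group):
            pid = f"{sub}{i}"
            short = i < n_per_group // 2
            score = (sep + 0.01 + 0.2 * rng.random() if short
                     else sep - 0.01 - 0.2 * rng.random())
            preds[pid] = score
            recist[pid] = sub
            rows[pid] = {"time": (rng.exponential(5) + 0.1 if short
                                  else 20 + rng.exponential(5)),
                         "event": True}
            k += 1
    frame = pd.DataFrame.from_dict(rows, orient="index")
    data = ck.LandmarkDataset(frame=frame,
                              excluded=pd.DataFrame(
                                  columns=["patient_id", "reason"]),
                              landmark_days=pd.Series(dtype=float),
                              endpoint="os")
    return pd.Series(preds), pd.Series(recist), data


class TestThresholds:
    def test_mpd_is_mean_of_subgroup_optima(self, monkeypatch):
        import ctdnakit.survival as surv

        preds, recist, data = _threshold_setup(sep=0.5)
        optima = iter([0.40, 0.20])
        monkeypatch.setattr(surv, "_optimal_logrank_split",
                            lambda *a, **k: next(optima))
        thr = ck.select_mpd_threshold(preds, recist, data)
        assert thr == pytest.approx(0.30)

    def test_optimal_split_matches_exhaustive_scan(self):
        """The returned cut equals the brute-force argmax of the log-rank
        statistic over interior candidate values (ties to the smaller)."""
        from ctdnakit.stats import logrank_counts
        from ctdnakit.survival import _optimal_logrank_split

        preds, recist, data = _threshold_setup(sep=0.5, seed=1)
        ids = [i for i in preds.index if recist[i] == "SD"]
        p = preds[ids]
        time = data.frame.loc[ids, "time"].to_numpy(float)
        event = data.frame.loc[ids, "event"].to_numpy(bool)
        got = _optimal_logrank_split(p, time, event, (0.1, 0.9))

        lo, hi = np.quantile(p, (0.1, 0.9))
        best_t, best = None, -np.inf
        for t in np.sort(np.unique(p[(p >= lo) & (p <= hi)])):
            grp = p.to_numpy() >= t
            if grp.all() or not grp.any():
                continue
            o, e_, v = logrank_counts(time, event, grp)
            if v > 0 and (o - e_) ** 2 / v > best:
                best_t, best = float(t), (o - e_) ** 2 / v
        assert got == best_t

    def test_small_subgroup_rejected_by_name(self):
        preds, recist, data = _threshold_setup(n_per_group=8)
        with pytest.raises(SubgroupSizeError, match="SD"):
            ck.select_mpd_threshold(preds, recist, data)

    def test_mresp_is_durable_fraction_percentile(self):
        preds = pd.Series(np.arange(1.0, 101.0),
                          index=[f"P{i}" for i in range(100)])
        times = np.r_[np.full(32, 2000.0), np.full(68, 100.0)]
        frame = pd.DataFrame({"time": times, "event": True},
                             index=preds.index)
        data = ck.LandmarkDataset(frame=frame, excluded=pd.DataFrame(),
                                  landmark_days=pd.Series(dtype=float),
                                  endpoint="os")
        thr = ck.select_mresp_threshold(preds, data)
        lo, hi = np.sort(preds)[31], np.sort(preds)[32]
        assert lo <= thr <= hi

    def test_mresp_median_for_half_durable(self):
        preds = pd.Series(np.linspace(-1, 1, 101),
                          index=[f"P{i}" for i in range(101)])
        times = np.r_[np.full(50, 2000.0), np.full(51, 10.0)]
        frame = pd.DataFrame({"time": times, "event": True},
                             index=preds.index)
        data = ck.LandmarkDataset(frame=frame, excluded=pd.DataFrame(),
                                  landmark_days=pd.Series(dtype=float),
                                  endpoint="os")
        thr = ck.select_mresp_threshold(preds, data,
                                        durable_horizon_days=1095.0)
        # durable fraction just under one half on 101 patients
        assert thr == pytest.approx(np.quantile(preds, 50 / 101))

    def test_no_durable_survivors_rejected(self):
        preds = pd.Series([0.1, 0.2], index=["a", "b"])
        frame = pd.DataFrame({"time": [10.0, 20.0], "event": True},
                             index=preds.index)
        data = ck.LandmarkDataset(frame=frame, excluded=pd.DataFrame(),
                                  landmark_days=pd.Series(dtype=float),
                                  endpoint="os")
        with pytest.raises(ValueError, match="durable"):
            ck.select_mresp_threshold(preds, data)


class TestMolecularResponseCalls:
    @pytest.fixture
    def model(self):
        m = ck.FinalModel(features=("f",), coefficients=np.array([1.0]),
                          medians=pd.Series({"f": 0.0}),
                          iqr=pd.Series({"f": 1.0}))
        m.mresp_threshold, m.mpd_threshold = 0.036, 0.298
        return m

    @pytest.mark.parametrize("score,call", [
        (0.5, "mPD"), (0.298, "mPD"), (0.01, "mResp"),
        (0.036, "mSD"), (0.1, "mSD"), (0.035999, "mResp"),
    ])
    def test_binning_rule(self, model, score, call):
        assert ck.call_molecular_response([score], model)[0] == call

    def test_unset_thresholds_rejected(self):
        m = ck.FinalModel(features=("f",), coefficients=np.array([1.0]),
                          medians=pd.Series({"f": 0.0}),
                          iqr=pd.Series({"f": 1.0}))
        with pytest.raises(ValueError):
            ck.call_molecular_response([0.1], m)


class TestTransfer:
    def _trained(self, seed=6):
        X, rec = simulate_survival_features(80, 3, {0: 1.0}, seed=seed)
        data = ck.landmark_rebaseline(rec, pd.Series(0.0, index=X.index),
                                      "os")
        m = FeatureMatrix(values=X, mask=X.isna())
        model = ck.fit_final_model(m, data, ["f0", "f1"])
        model.mresp_threshold = float(np.quantile(
            model.score(X), 0.32))
        model.mpd_threshold = float(np.quantile(model.score(X), 0.7))
        return model, m

    def test_identity_transfer_reproduces_scores(self):
        model, m = self._trained()
        out = ck.transfer_model(model, m)
        pd.testing.assert_series_equal(out["score"],
                                       model.score(m.values),
                                       check_names=False)

    def test_missing_feature_errors_with_names(self):
        model, m = self._trained()
        short = FeatureMatrix(values=m.values[["f0"]],
                              mask=m.values[["f0"]].isna())
        with pytest.raises(ValueError, match="f1"):
            ck.transfer_model(model, short)

    def test_external_cohort_risk_groups_separate(self):
        """Transferred calls stratify survival in a shifted external
        cohort (generative oracle)."""
        from ctdnakit.stats import logrank_two_sided

        model, _ = self._trained()
        Xe, rece = simulate_survival_features(300, 3, {0: 1.3}, seed=99)
        ext = FeatureMatrix(values=Xe, mask=Xe.isna())
        out = ck.transfer_model(model, ext)
        high = (out["call"] == "mPD").to_numpy()
        assert 0 < high.sum() < len(high)
        p = logrank_two_sided(rece["os_time"].to_numpy(),
                              rece["os_event"].to_numpy(bool), high)
        assert p < 0.05
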