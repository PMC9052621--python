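import numpy as np
import pandas as pd
import pytest
from scipy import stats

from _oracles import auc_pairwise_oracle
from stemsig.containers import ExpressionMatrix
from stemsig.response import (
    KernelNaiveBayes,
    KernelNBResults,
    batch_correct,
    km_logrank,
    predict_response,
    roc_auc,
    split_cohort,
    train_nb,
    tune_bandwidth,
)


def _bulk(x):
    x = np.asarray(x, dtype=float)
    return ExpressionMatrix(
        x,
        pd.Index([f"g{i}" for i in range(x.shape[0])]),
        pd.Index([f"s{j}" for j in range(x.shape[1])]),
        orientation="genes_by_samples",
        layer_tag="tpm_like",
    )


class TestBatchCorrect:
    def test_single_batch_identity(self, rng):
        em = _bulk(rng.normal(5, 1, size=(10, 6)))
        out = batch_correct(em, ["b1"] * 6, allow_single=True)
        np.testing.assert_allclose(out.dense(), em.dense())

    def test_single_batch_without_flag_rejected(self, rng):
        with pytest.raises(ValueError, match="2 batches"):
            batch_correct(_bulk(rng.normal(size=(5, 6))), ["b1"] * 6)

    def test_pure_constant_offset_removed_exactly(self, rng):
        # two batches differing only by a constant gene-wise offset, no
        # other signal: correction equalises per-batch gene means exactly
        base = rng.normal(5, 1, size=30)
        x = np.repeat(base[:, None], 40, axis=1)
        offset = rng.normal(0, 2, size=30)
        x[:, 20:] += offset[:, None]
        out = batch_correct(_bulk(x), ["a"] * 20 + ["b"] * 20).dense()
        gap = out[:, :20].mean(axis=1) - out[:, 20:].mean(axis=1)
        assert np.abs(gap).max() < 1e-6

    def test_offset_with_noise_mostly_removed(self, rng):
        # with within-batch noise, empirical-Bayes shrinkage leaves only a
        # small residual of the planted two-unit offsets
        x = rng.normal(5, 1, size=(30, 40))
        offset = rng.normal(0, 2, size=30)
        x[:, 20:] += offset[:, None]
        out = batch_correct(_bulk(x), ["a"] * 20 + ["b"] * 20).dense()
        gap = out[:, :20].mean(axis=1) - out[:, 20:].mean(axis=1)
        assert np.abs(gap).max() < 0.3
        assert np.abs(gap).mean() < np.abs(offset).mean() / 5

    def test_within_batch_order_preserved(self, rng):
        x = rng.normal(5, 1, size=(10, 30))
        x[:, 15:] += 3.0
        out = batch_correct(_bulk(x), ["a"] * 15 + ["b"] * 15).dense()
        for g in range(10):
            assert (np.argsort(out[g, :15]) == np.argsort(x[g, :15])).all()

    def test_degenerate_gene_location_only(self, rng):
        x = rng.normal(5, 1, size=(6, 20))
        x[0] = np.where(np.arange(20) < 10, 2.0, 7.0)  # constant within each batch
        out = batch_correct(_bulk(x), ["a"] * 10 + ["b"] * 10).dense()
        assert np.isfinite(out).all()
        # both batches pulled to the common mean for the degenerate gene
        np.testing.assert_allclose(out[0], np.full(20, 4.5), atol=1e-9)


class TestSplitCohort:
    @pytest.mark.parametrize("n,frac,expected", [(772, 0.2, (618, 154)), (10, 0.2, (8, 2))])
    def test_split_sizes(self, n, frac, expected):
        train, val = split_cohort([f"s{i}" for i in range(n)], frac, seed=1)
        assert (len(train), len(val)) == expected
        assert set(train) | set(val) == {f"s{i}" for i in range(n)}
        assert not set(train) & set(val)

    def test_determinism_and_seed_sensitivity(self):
        ids = [f"s{i}" for i in range(100)]
        assert split_cohort(ids, 0.2, seed=3) == split_cohort(ids, 0.2, seed=3)
        assert split_cohort(ids, 0.2, seed=3) != split_cohort(ids, 0.2, seed=4)

    def test_stratified_split_balances_classes(self):
        ids = [f"s{i}" for i in range(100)]
        y = [i < 20 for i in range(100)]
        train, val = split_cohort(ids, 0.2, seed=5, stratify=y)
        val_pos = sum(1 for s in val if int(s[1:]) < 20)
        assert len(val) == 20
        assert val_pos == 4  # 20% of the 20 positives


class TestKernelNaiveBayes:
    def test_separated_classes_confident_posterior(self):
        X = pd.DataFrame({"f": [0.0, 0.0, 0.0, 10.0, 10.0, 10.0]})
        y = [False, False, False, True, True, True]
        model = train_nb(X, y)
        p0 = model.predict_proba(pd.DataFrame({"f": [0.0]}))[0]
        assert p0 < 0.001  # P(responder) at the non-responder mode

    def test_gaussian_form_matches_closed_form_bayes(self, rng):
        n = 400
        y = rng.uniform(size=n) < 0.5
        X = pd.DataFrame({
            "a": np.where(y, rng.normal(1, 1, n), rng.normal(-1, 1, n)),
            "b": np.where(y, rng.normal(0.5, 2, n), rng.normal(0, 2, n)),
        })
        model = train_nb(X, y, use_kernel=False)
        post = model.predict_proba(X)
        # closed-form naive Bayes with the fitted class-conditional Gaussians
        logp = np.log(model.priors[1]) - np.log(model.priors[0])
        for f in ("a", "b"):
            mr, sr = model.gaussians["R"][f]
            mn, sn = model.gaussians["NR"][f]
            logp = logp + stats.norm.logpdf(X[f], mr, sr) - stats.norm.logpdf(X[f], mn, sn)
        expected = 1.0 / (1.0 + np.exp(-logp))
        np.testing.assert_allclose(post, expected, atol=1e-6)

    def test_duplicating_training_samples_is_noop(self, rng):
        n = 60
        y = np.arange(n) % 2 == 0
        X = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
        m1 = train_nb(X, y)
        m2 = train_nb(pd.concat([X, X], ignore_index=True), np.concatenate([y, y]))
        Xnew = pd.DataFrame({"a": rng.normal(size=10), "b": rng.normal(size=10)})
        np.testing.assert_allclose(m1.predict_proba(Xnew), m2.predict_proba(Xnew), atol=1e-9)

    def test_empty_feature_set_returns_prior(self, rng):
        y = np.array([True] * 3 + [False] * 7)
        X = pd.DataFrame(index=range(10))
        model = KernelNaiveBayes(X, y).fit()
        post = model.predict_proba(pd.DataFrame(index=range(4)))
        np.testing.assert_allclose(post, np.full(4, 0.3), atol=1e-12)

    def test_symmetric_problem_posterior_half_at_midpoint(self):
        X = pd.DataFrame({"f": [-2.0, -1.0, -1.5, 2.0, 1.0, 1.5]})
        y = [False, False, False, True, True, True]
        model = train_nb(X, y)
        assert model.predict_proba(pd.DataFrame({"f": [0.0]}))[0] == pytest.approx(0.5, abs=1e-9)
        # tie at exactly 0.5 is called NR
        preds = predict_response(model, pd.DataFrame({"f": [0.0]}))
        assert preds["label"].iloc[0] == "NR"

    def test_matches_bruteforce_density_product(self, rng):
        n = 30
        y = np.arange(n) % 2 == 0
        X = pd.DataFrame(rng.normal(size=(n, 3)), columns=list("abc"))
        model = train_nb(X, y, bandwidth_adjust=0.75)
        xq = pd.DataFrame(rng.normal(size=(5, 3)), columns=list("abc"))
        post = model.predict_proba(xq)
        for i in range(5):
            lik = {}
            for cls, mask in (("R", y), ("NR", ~y)):
                prod = 1.0
                for f in "abc":
                    pts = X.loc[mask, f].to_numpy()
                    h = model.bandwidths[cls][f]
                    prod *= np.mean(stats.norm.pdf((xq[f].iloc[i] - pts) / h)) / h
                lik[cls] = prod
            expected = (
                model.priors[1] * lik["R"]
                / (model.priors[1] * lik["R"] + model.priors[0] * lik["NR"])
            )
            assert post[i] == pytest.approx(expected, rel=1e-9)

    def test_single_class_rejected(self, rng):
        X = pd.DataFrame({"f": rng.normal(size=5)})
        with pytest.raises(ValueError, match="both classes"):
            train_nb(X, [True] * 5)

    def test_json_roundtrip(self, tmp_path, rng):
        n = 40
        y = np.arange(n) % 2 == 0
        X = pd.DataFrame(rng.normal(size=(n, 2)), columns=["a", "b"])
        model = train_nb(X, y)
        model.to_json(tmp_path / "m.json")
        back = KernelNBResults.from_json(tmp_path / "m.json")
        Xq = pd.DataFrame(rng.normal(size=(8, 2)), columns=["a", "b"])
        np.testing.assert_allclose(model.predict_proba(Xq), back.predict_proba(Xq))

    def test_summary_mentions_parameters(self, rng):
        n = 20
        model = train_nb(pd.DataFrame({"f": rng.normal(size=n)}), np.arange(n) % 2 == 0)
        s = model.summary()
        assert "bandwidth_adjust" in s and "0.75" in s

    def test_tune_bandwidth_returns_grid_member(self, rng):
        n = 80
        y = np.arange(n) % 2 == 0
        X = pd.DataFrame({"f": rng.normal(size=n) + y})
        grid = (0.5, 1.0)
        assert tune_bandwidth(X, y, grid=grid, k=4, seed=0) in grid


class TestRocAuc:
    def test_perfect_and_degenerate(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [False, False, True, True]).auc == 1.0
        assert roc_auc([0.5] * 6, [True, False, True, False, True, False]).auc == 0.5

    def test_matches_pairwise_oracle(self, rng):
        s = np.round(rng.normal(size=60), 1)  # rounding forces ties
        y = rng.uniform(size=60) < 0.4
        res = roc_auc(s, y)
        assert res.auc == pytest.approx(auc_pairwise_oracle(s, y), abs=1e-12)

    def test_auc_equals_trapezoid_area_and_curve_monotone(self, rng):
        s = rng.normal(size=80)
        y = rng.uniform(size=80) < 0.5
        res = roc_auc(s, y)
        assert (np.diff(res.fpr) >= 0).all()
        assert (np.diff(res.tpr) >= 0).all()
        assert res.auc == pytest.approx(np.trapezoid(res.tpr, res.fpr), abs=1e-12)

    def test_invariant_to_monotone_transform(self, rng):
        s = rng.normal(size=50)
        y = rng.uniform(size=50) < 0.5
        assert roc_auc(np.exp(s), y).auc == pytest.approx(roc_auc(s, y).auc)


class TestSurvival:
    def test_identical_groups_null_result(self):
        t = np.array([5.0, 8.0, 12.0, 20.0] * 2)
        e = np.array([1, 1, 0, 1] * 2)
        g = ["A"] * 4 + ["B"] * 4
        res = km_logrank(t, e, g)
        assert res.logrank_chi2 == pytest.approx(0.0, abs=1e-9)
        assert res.hr == pytest.approx(1.0, abs=1e-6)

    def test_hand_computed_logrank_toy(self):
        # times 1,2,3,4 all events; groups A,A,B,B
        # O-E for group A: at t=1 (1 - 2/4), t=2 (1 - 1/3); var = 1/4 + 2/9
        res = km_logrank([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1], ["A", "A", "B", "B"])
        o_minus_e = (1 - 2 / 4) + (1 - 1 / 3)
        var = (2 * 2 / (4 * 4)) + (1 * 2 * 2 * 1 / (3 * 3 * 2))
        assert res.logrank_chi2 == pytest.approx(o_minus_e**2 / var, rel=1e-6)

    def test_breslow_hr_matches_lifelines_on_continuous_times(self, rng):
        from lifelines import CoxPHFitter

        n = 120
        g = rng.uniform(size=n) < 0.5
        t = rng.exponential(1.0 / np.where(g, 2.0, 1.0))
        e = (t < 2.0).astype(int)
        t = np.minimum(t, 2.0)
        res = km_logrank(t, e, np.where(g, "high", "low"), reference="low")
        df = pd.DataFrame({"t": t, "e": e, "x": g.astype(int)})
        cph = CoxPHFitter().fit(df, duration_col="t", event_col="e")
        assert res.hr == pytest.approx(float(np.exp(cph.params_["x"])), rel=1e-4)

    def test_hazard_ratio_recovery(self):
        rng = np.random.default_rng(42)
        n = 500
        g = rng.uniform(size=n) < 0.5
        lam = np.where(g, 2.0, 1.0) * np.log(2) / 24.0
        t = rng.exponential(1.0 / lam)
        e = (t <= 36.0).astype(int)
        res = km_logrank(np.minimum(t, 36.0), e, np.where(g, "high", "low"), reference="low")
        assert 1.7 <= res.hr <= 2.35
        assert res.logrank_p < 0.01

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="events"):
            km_logrank([1.0, 2.0], [0, 0], ["A", "B"])

    def test_reference_flips_hr(self, rng):
        n = 80
        g = rng.uniform(size=n) < 0.5
        t = rng.exponential(1.0 / np.where(g, 2.0, 1.0))
        e = np.ones(n, dtype=int)
        labels = np.where(g, "high", "low")
        hr_low_ref = km_logrank(t, e, labels, reference="low").hr
        hr_high_ref = km_logrank(t, e, labels, reference="high").hr
        assert hr_low_ref == pytest.approx(1.0 / hr_high_ref, rel=1e-6)
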