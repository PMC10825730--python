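"""Splitting, random-forest evaluation, rank-sum selection, cost wrapper."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import roc_auc_score

import methylpanel as mp
from methylpanel import classify
from methylpanel.classify import CostModel
from methylpanel.collapse import GeneMatrix
from methylpanel.stability import CandidateList


def brute_force_auc(y, scores):
    """Mann-Whitney AUC with half-credit ties."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestSplitCohort:
    def test_hgd_always_held_out(self, small_cohort):
        split = classify.split_cohort(small_cohort, seed=1)
        hgd = small_cohort.loc[small_cohort["diagnosis"] == "HGD",
                               "sample_id"]
        assert (split.loc[hgd] == "hgd_holdout").all()
        assert (split[split != "hgd_holdout"]
                .isin(classify.SPLIT_NAMES).all())

    def test_stratified_proportions(self, small_cohort):
        split = classify.split_cohort(small_cohort, seed=2)
        merged = small_cohort.set_index("sample_id").join(split)
        for diagnosis, grp in merged.groupby("diagnosis"):
            if diagnosis == "HGD":
                continue
            n = len(grp)
            for name, frac in zip(classify.SPLIT_NAMES, (0.64, 0.16, 0.20)):
                got = (grp["split"] == name).sum()
                assert abs(got - frac * n) <= 1

    def test_everything_to_discovery(self, small_cohort):
        split = classify.split_cohort(small_cohort, fractions=(1.0, 0.0, 0.0),
                                      seed=3)
        non_hgd = split[split != "hgd_holdout"]
        assert (non_hgd == "discovery").all()

    def test_deterministic(self, small_cohort):
        a = classify.split_cohort(small_cohort, seed=4)
        b = classify.split_cohort(small_cohort, seed=4)
        pd.testing.assert_series_equal(a, b)

    def test_bad_fractions_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            classify.split_cohort(small_cohort, fractions=(0.5, 0.2, 0.2))


def _classification_fixture(rng, n=180, signal=2.0):
    ids = [f"s{i:03d}" for i in range(n)]
    diagnosis = pd.Series(
        rng.choice(["HV", "NPD", "NDBE", "IMC", "INVASIVE"], n,
                   p=[0.28, 0.16, 0.2, 0.11, 0.25]), index=ids)
    y = diagnosis.isin({"IMC", "INVASIVE"}).astype(int)
    genes = [f"G{i}" for i in range(4)]
    vals = rng.standard_normal((4, n)) + signal * y.to_numpy()[None, :]
    gm = GeneMatrix(pd.DataFrame(vals, index=genes, columns=ids),
                    chosen_probe=pd.Series(genes, index=genes))
    covs = pd.DataFrame({"age": rng.normal(65, 10, n),
                         "sex": rng.choice(["F", "M"], n),
                         "epithelial": rng.beta(4, 6, n)}, index=ids)
    cohort = pd.DataFrame({"sample_id": ids,
                           "diagnosis": diagnosis.to_numpy()})
    split = classify.split_cohort(cohort, seed=5)
    cand = CandidateList(k=2, N=2, genes=genes[:3])
    return cand, gm, covs, diagnosis, split


class TestTrainAndEvaluate:
    def test_perfect_separation_auc_one(self):
        rng = np.random.default_rng(20)
        cand, gm, covs, diagnosis, split = _classification_fixture(
            rng, signal=0.0)
        y = classify.binarize_diagnosis(diagnosis)
        gm.values.iloc[0] = y.to_numpy() * 10.0  # one perfectly separating gene
        ev = classify.train_and_evaluate(cand, gm, covs, diagnosis, split,
                                         rf_params={"n_estimators": 100},
                                         n_boot=0, seed=1)
        for name in classify.SPLIT_NAMES:
            assert ev.metrics[name]["auc"] == pytest.approx(1.0)

    def test_out_of_fold_covers_discovery_once(self):
        rng = np.random.default_rng(21)
        cand, gm, covs, diagnosis, split = _classification_fixture(rng)
        ev = classify.train_and_evaluate(cand, gm, covs, diagnosis, split,
                                         rf_params={"n_estimators": 30},
                                         n_boot=0, seed=2)
        y, p = ev.probabilities["discovery"]
        n_disc = (split == "discovery").sum()
        assert len(p) == n_disc
        assert np.isfinite(p).all()

    def test_permuted_labels_near_half(self):
        rng = np.random.default_rng(22)
        cand, gm, covs, diagnosis, split = _classification_fixture(
            rng, signal=0.0)
        # covariates deliberately uninformative too
        covs["age"] = rng.normal(65, 10, len(covs))
        ev = classify.train_and_evaluate(cand, gm, covs, diagnosis, split,
                                         rf_params={"n_estimators": 100},
                                         n_boot=0, seed=3)
        y, p = ev.probabilities["discovery"]
        n1, n0 = int(y.sum()), int((1 - y).sum())
        se = np.sqrt((n1 + n0 + 1) / (12 * n1 * n0))
        assert abs(ev.metrics["discovery"]["auc"] - 0.5) < 3 * se

    def test_auc_matches_mann_whitney(self):
        rng = np.random.default_rng(23)
        cand, gm, covs, diagnosis, split = _classification_fixture(rng)
        ev = classify.train_and_evaluate(cand, gm, covs, diagnosis, split,
                                         rf_params={"n_estimators": 30},
                                         n_boot=0, seed=4)
        for name in classify.SPLIT_NAMES:
            y, p = ev.probabilities[name]
            assert ev.metrics[name]["auc"] == pytest.approx(
                brute_force_auc(np.asarray(y), np.asarray(p)), abs=1e-10)

    def test_bootstrap_ci_brackets_point_estimate(self):
        rng = np.random.default_rng(24)
        cand, gm, covs, diagnosis, split = _classification_fixture(rng)
        ev = classify.train_and_evaluate(cand, gm, covs, diagnosis, split,
                                         rf_params={"n_estimators": 30},
                                         n_boot=200, seed=5)
        lo, hi = ev.metrics["validation"]["ci"]
        assert lo <= ev.metrics["validation"]["auc"] <= hi


class TestRankClassifiers:
    def _ev(self, k, N, aucs):
        cand = CandidateList(k=k, N=N, genes=[f"G{k}_{N}_{i}"
                                              for i in range(N)])
        metrics = {name: {"auc": a, "sensitivity": np.nan,
                          "specificity": np.nan, "ci": None}
                   for name, a in zip(classify.SPLIT_NAMES, aucs)}
        arr = np.array(aucs)
        return classify.CandidateEvaluation(
            candidate=cand, metrics=metrics, mean_auc=float(arr.mean()),
            var_auc=float(arr.var(ddof=1)))

    def test_single_candidate_wins(self):
        ev = self._ev(2, 2, (0.7, 0.7, 0.7))
        best, table = classify.rank_classifiers([ev])
        assert best is ev

    def test_consistent_beats_spiky(self):
        # A: high discovery only; B: consistent -> B has rank_sum 2 vs 4
        a = self._ev(3, 2, (0.9, 0.5, 0.5))
        b = self._ev(4, 2, (0.7, 0.68, 0.69))
        best, table = classify.rank_classifiers([a, b])
        assert best is b
        assert b.rank_sum == 2.0
        assert a.rank_sum == 4.0

    def test_identical_candidates_tie_break(self):
        evs = [self._ev(k, 2, (0.7, 0.7, 0.7)) for k in (5, 3, 4)]
        best, _ = classify.rank_classifiers(evs)
        assert best.candidate.k == 3  # lexicographic (k, N) tie-break

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            classify.rank_classifiers([])


class TestCostModel:
    def test_weight_one_threshold_half(self):
        assert CostModel(1.0).threshold == pytest.approx(0.5)

    def test_weight_twenty_threshold(self):
        assert CostModel(20.0).threshold == pytest.approx(1 / 21)

    def test_weight_below_one_rejected(self):
        with pytest.raises(ValueError):
            CostModel(0.5)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.floats(1.0, 200.0), st.floats(1.0, 200.0))
    def test_threshold_decreasing_in_weight(self, w1, w2):
        lo, hi = sorted((w1, w2))
        assert CostModel(hi).threshold <= CostModel(lo).threshold

    def test_all_above_threshold(self):
        p = np.full(10, 0.9)
        calls = classify.cost_sensitive_predict(p, CostModel(20.0))
        assert calls.sum() == 10


class TestCostSweep:
    def test_monotone_in_weight(self):
        rng = np.random.default_rng(25)
        y = (rng.random(200) < 0.3).astype(int)
        p = np.clip(rng.normal(0.3 + 0.3 * y, 0.2), 0, 1)
        sweep = classify.cost_sweep({"validation": (y, p)},
                                    weights=(1, 2, 5, 10, 20, 50, 100))
        sens = sweep["validation_sensitivity"].to_numpy()
        spec = sweep["validation_specificity"].to_numpy()
        assert (np.diff(sens) >= 0).all()
        assert (np.diff(spec) <= 0).all()
        # oracle: direct threshold enumeration
        for w, s in zip(sweep["weight"], sens):
            thr = 1 / (1 + w)
            assert s == pytest.approx(((p >= thr) & (y == 1)).sum()
                                      / (y == 1).sum())

    def test_weight_one_equals_base_model(self):
        y = np.array([0, 0, 1, 1])
        p = np.array([0.2, 0.6, 0.4, 0.9])
        sweep = classify.cost_sweep({"testing": (y, p)}, weights=(1,))
        assert sweep.loc[0, "testing_sensitivity"] == 0.5
        assert sweep.loc[0, "testing_specificity"] == 0.5

    def test_hgd_fraction_reported(self):
        y = np.ones(6, dtype=int)
        p = np.array([0.02, 0.1, 0.2, 0.5, 0.7, 0.9])
        sweep = classify.cost_sweep({"hgd_holdout": (y, p)},
                                    weights=(1, 20))
        assert sweep.loc[0, "hgd_called_cancer"] == pytest.approx(3 / 6)
        assert sweep.loc[1, "hgd_called_cancer"] == pytest.approx(5 / 6)

    def test_unsorted_weights_rejected(self):
        with pytest.raises(ValueError):
            classify.cost_sweep({}, weights=(5, 1))

    def test_subgroup_sensitivity_consistent_with_pooled(self):
        rng = np.random.default_rng(26)
        diagnosis = pd.Series(rng.choice(["IMC", "INVASIVE"], 40))
        calls = pd.Series(rng.integers(0, 2, 40))
        sub = classify.subgroup_sensitivity(diagnosis, calls)
        n_imc = (diagnosis == "IMC").sum()
        n_inv = (diagnosis == "INVASIVE").sum()
        pooled = (sub["IMC"] * n_imc + sub["INVASIVE"] * n_inv) / 40
        assert pooled == pytest.approx(calls.mean())
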