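"""Cohort splitting, random-forest evaluation and cost-sensitive decisions.

The cohort is stratified by diagnosis subclass into discovery / testing /
validation sets (HGD samples are always held out entirely). Each candidate
gene list plus age, sex and epithelial fraction feeds a random forest:
discovery performance is the stratified tenfold out-of-fold AUC, the forest
is then refit on all of discovery and applied to the testing and validation
sets. Across candidates, the winner minimizes the sum of two ranks — rank
of descending mean AUC and rank of ascending across-dataset AUC variance —
so it must both perform and generalize consistently.

Cancer costs more to miss than a control costs to flag: with a false
negative weighted w times a false positive, expected-cost minimization for
two classes calls cancer whenever the predicted probability exceeds
1/(1+w). The study's weight of 20 (threshold 1/21) targets sensitivity 0.9.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .collapse import GeneMatrix
from .simulate import CANCER_CLASSES
from .stability import CandidateList

SPLIT_NAMES = ("discovery", "testing", "validation")
DEFAULT_FRACTIONS = (0.64, 0.16, 0.20)
DEFAULT_RF_PARAMS = {"n_estimators": 500, "max_features": "sqrt"}


def binarize_diagnosis(diagnosis: pd.Series) -> pd.Series:
    """IMC and invasive adenocarcinoma = 1; HV, NPD, NDBE = 0."""
    return diagnosis.isin(CANCER_CLASSES).astype(int)


def split_cohort(cohort: pd.DataFrame,
                 fractions: tuple[float, float, float] = DEFAULT_FRACTIONS,
                 seed: int = 0) -> pd.Series:
    """Stratified discovery/testing/validation split; HGD fully held out.

    Within every diagnosis subclass, samples are shuffled and allocated by
    largest remainder so subclass proportions agree across splits to within
    one sample. Strata smaller than 3 go entirely to discovery.
    """
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5139]))
    assignment = pd.Series(index=cohort["sample_id"].to_numpy(), dtype=object,
                           name="split")
    for diagnosis, group in cohort.groupby("diagnosis"):
        ids = group["sample_id"].to_numpy()
        if diagnosis == "HGD":
            assignment.loc[ids] = "hgd_holdout"
            continue
        ids = ids[rng.permutation(len(ids))]
        n = len(ids)
        if n < 3:
            warnings.warn(f"stratum {diagnosis} smaller than 3: all to discovery")
            assignment.loc[ids] = "discovery"
            continue
        exact = np.array(fractions) * n
        counts = np.floor(exact).astype(int)
        remainder = exact - counts
        for _ in range(n - counts.sum()):
            j = int(np.argmax(remainder))
            counts[j] += 1
            remainder[j] = -1
        start = 0
        for name, c in zip(SPLIT_NAMES, counts):
            assignment.loc[ids[start:start + c]] = name
            start += c
    return assignment


@dataclass
class CandidateEvaluation:
    candidate: CandidateList
    metrics: dict[str, dict]        # dataset -> auc/sensitivity/specificity/ci
    mean_auc: float
    var_auc: float
    rank_mean: float = np.nan
    rank_var: float = np.nan
    rank_sum: float = np.nan

    @property
    def aucs(self) -> list[float]:
        return [self.metrics[name]["auc"] for name in SPLIT_NAMES]


def _sens_spec(y: np.ndarray, calls: np.ndarray) -> tuple[float, float]:
    pos = y == 1
    neg = ~pos
    sens = float((calls[pos] == 1).mean()) if pos.any() else np.nan
    spec = float((calls[neg] == 0).mean()) if neg.any() else np.nan
    return sens, spec


def _stratified_bootstrap_auc_ci(y: np.ndarray, p: np.ndarray, n_boot: int,
                                 rng: np.random.Generator,
                                 level: float = 0.95) -> tuple[float, float]:
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        ip = rng.choice(pos, size=len(pos), replace=True)
        ineg = rng.choice(neg, size=len(neg), replace=True)
        idx = np.concatenate([ip, ineg])
        aucs[b] = roc_auc_score(y[idx], p[idx])
    alpha = (1 - level) / 2
    return (float(np.quantile(aucs, alpha)),
            float(np.quantile(aucs, 1 - alpha)))


def candidate_features(candidate_genes: list[str], gm: GeneMatrix,
                       covariates: pd.DataFrame) -> pd.DataFrame:
    """Samples x features table: gene values plus age, sex (0/1), epithelial."""
    feats = gm.values.loc[candidate_genes].T.copy()
    covs = covariates.loc[feats.index].copy()
    if covs["sex"].dtype == object:
        covs["sex"] = covs["sex"].map({"F": 0.0, "M": 1.0})
    for col in covs.columns:
        feats[f"cov_{col}"] = covs[col].astype(float)
    return feats


def train_and_evaluate(candidate: CandidateList, gm: GeneMatrix,
                       covariates: pd.DataFrame, diagnosis: pd.Series,
                       split: pd.Series, rf_params: dict | None = None,
                       n_boot: int = 2000, seed: int = 0
                       ) -> CandidateEvaluation:
    """Tenfold out-of-fold discovery AUC plus held-out testing/validation.

    Sensitivity/specificity are reported at the base probability threshold
    0.5. Bootstrap AUC confidence intervals (stratified percentile) are
    computed when ``n_boot`` > 0. The refit forest and the per-dataset
    probability vectors are attached for downstream cost sweeps.
    """
    params = dict(DEFAULT_RF_PARAMS)
    if rf_params:
        params.update(rf_params)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xF0E1]))
    rf_seed = int(rng.integers(0, 2**31 - 1))

    feats = candidate_features(candidate.genes, gm, covariates)
    y = binarize_diagnosis(diagnosis).loc[feats.index]
    ids_by_split = {name: split.index[split == name].intersection(feats.index)
                    for name in SPLIT_NAMES}

    Xd = feats.loc[ids_by_split["discovery"]].to_numpy()
    yd = y.loc[ids_by_split["discovery"]].to_numpy()

    oof = np.full(len(yd), np.nan)
    for attempt in range(10):
        skf = StratifiedKFold(n_splits=10, shuffle=True,
                              random_state=rf_seed + attempt)
        ok = True
        for tr, te in skf.split(Xd, yd):
            if len(np.unique(yd[tr])) < 2:
                ok = False
                break
            clf = RandomForestClassifier(random_state=rf_seed, **params)
            clf.fit(Xd[tr], yd[tr])
            oof[te] = clf.predict_proba(Xd[te])[:, 1]
        if ok:
            if attempt:
                warnings.warn("refolded cross-validation after one-class fold")
            break
    assert not np.isnan(oof).any()

    final = RandomForestClassifier(random_state=rf_seed, **params)
    final.fit(Xd, yd)

    probs = {"discovery": (yd, oof)}
    for name in ("testing", "validation"):
        ids = ids_by_split[name]
        ye = y.loc[ids].to_numpy()
        pe = final.predict_proba(feats.loc[ids].to_numpy())[:, 1] \
            if len(ids) else np.array([])
        probs[name] = (ye, pe)

    metrics = {}
    for name, (ye, pe) in probs.items():
        auc = roc_auc_score(ye, pe) if len(np.unique(ye)) == 2 else np.nan
        sens, spec = _sens_spec(ye, (pe >= 0.5).astype(int))
        ci = None
        if n_boot > 0 and len(np.unique(ye)) == 2:
            ci = _stratified_bootstrap_auc_ci(ye, pe, n_boot, rng)
        metrics[name] = {"auc": float(auc), "sensitivity": sens,
                         "specificity": spec, "ci": ci}

    aucs = np.array([metrics[n]["auc"] for n in SPLIT_NAMES])
    ev = CandidateEvaluation(candidate=candidate, metrics=metrics,
                             mean_auc=float(aucs.mean()),
                             var_auc=float(aucs.var(ddof=1)))
    ev.model = final
    ev.probabilities = probs
    ev.features = feats
    return ev


def rank_classifiers(evals: list[CandidateEvaluation]
                     ) -> tuple[CandidateEvaluation, pd.DataFrame]:
    """Rank-sum model selection across candidates.

    rank_mean ranks descending mean AUC (1 = best), rank_var ranks ascending
    across-dataset variance (1 = most consistent); the winner minimizes
    their sum, with ties broken by higher mean AUC, then shorter gene list,
    then lexicographic (k, N).
    """
    if len(evals) == 0:
        raise ValueError("no evaluations to rank")
    mean_auc = np.array([e.mean_auc for e in evals])
    var_auc = np.array([e.var_auc for e in evals])
    rank_mean = rankdata(-mean_auc, method="average")
    rank_var = rankdata(var_auc, method="average")
    for e, rm, rv in zip(evals, rank_mean, rank_var):
        e.rank_mean = float(rm)
        e.rank_var = float(rv)
        e.rank_sum = float(rm + rv)
    order = sorted(
        range(len(evals)),
        key=lambda i: (evals[i].rank_sum, -evals[i].mean_auc,
                       len(evals[i].candidate.genes),
                       evals[i].candidate.k, evals[i].candidate.N))
    table = pd.DataFrame({
        "k": [e.candidate.k for e in evals],
        "N": [e.candidate.N for e in evals],
        "n_genes": [len(e.candidate.genes) for e in evals],
        "mean_auc": mean_auc, "var_auc": var_auc,
        "rank_mean": rank_mean, "rank_var": rank_var,
        "rank_sum": rank_mean + rank_var,
    })
    return evals[order[0]], table


@dataclass
class CostModel:
    """Misclassification-cost ratio w of a missed cancer to a false alarm."""

    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.weight < 1:
            raise ValueError("cost weight must be >= 1")

    @property
    def threshold(self) -> float:
        return 1.0 / (1.0 + self.weight)


def cost_sensitive_predict(probabilities: np.ndarray,
                           cost: CostModel | float) -> np.ndarray:
    """Call cancer whenever p >= 1/(1+w)."""
    if not isinstance(cost, CostModel):
        cost = CostModel(weight=float(cost))
    p = np.asarray(probabilities, dtype=float)
    return (p >= cost.threshold).astype(int)


def cost_sweep(probs_by_dataset: dict[str, tuple[np.ndarray, np.ndarray]],
               weights=(1, 2, 5, 10, 20, 50)) -> pd.DataFrame:
    """Sensitivity/specificity per dataset over a grid of cost weights.

    ``probs_by_dataset`` maps dataset name -> (labels, probabilities); an
    ``hgd_holdout`` entry reports the fraction of HGD samples called cancer
    instead of sensitivity/specificity.
    """
    weights = list(weights)
    if weights != sorted(weights):
        raise ValueError("weights must be sorted ascending")
    rows = []
    for w in weights:
        row: dict[str, float] = {"weight": w}
        for name, (ye, pe) in probs_by_dataset.items():
            calls = cost_sensitive_predict(pe, CostModel(float(w)))
            if name == "hgd_holdout":
                row["hgd_called_cancer"] = float(calls.mean()) if len(calls) else np.nan
                continue
            sens, spec = _sens_spec(np.asarray(ye), calls)
            row[f"{name}_sensitivity"] = sens
            row[f"{name}_specificity"] = spec
        rows.append(row)
    return pd.DataFrame(rows)


def subgroup_sensitivity(diagnosis: pd.Series, calls: pd.Series) -> pd.Series:
    """Sensitivity within each cancer subclass (IMC, invasive)."""
    out = {}
    for cls in sorted(CANCER_CLASSES):
        mask = diagnosis == cls
        out[cls] = float(calls[mask].mean()) if mask.any() else np.nan
    return pd.Series(out, name="sensitivity")
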