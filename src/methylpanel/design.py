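"""Case-control matching and array plate layout optimization.

Matching works in a weighted covariate space: each continuous covariate is
z-scored over the full cohort and multiplied by an importance weight, sex is
coded 0/1 and weighted, and the match distance is the Euclidean norm of the
difference. Each cancer case (IMC or invasive), visited in random order, is
greedily matched without replacement to its nearest unused control from each
control diagnosis class.

Plate layout starts from matched clusters randomly assigned to array rows
and then hill-climbs: random pairs of samples are swapped and the swap is
kept only if it lowers a global covariate-imbalance objective, defined as
the sum over all pairs of batch units (rows within and across plates, and
whole plates) of |t| statistics for continuous covariates plus chi-square
statistics for sex.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import CANCER_CLASSES, CONTROL_CLASSES, COVARIATE_COLUMNS

#: importance weights of the matching covariates
DEFAULT_MATCH_WEIGHTS = {
    "sex": 5.0, "age": 3.0, "bmi": 3.0, "ppi": 3.0,
    "smoking": 1.0, "alcohol": 0.5, "heartburn": 3.0,
}


@dataclass
class MatchedCluster:
    """One cancer index case plus one control per control class."""

    case: str
    controls: dict[str, str]

    def members(self) -> list[str]:
        return [self.case] + list(self.controls.values())


@dataclass
class PlateLayout:
    assignment: pd.DataFrame          # sample_id, plate, row
    heterogeneity_score: float
    trace: list[tuple[int, float]] = field(default_factory=list)


def cohort_normalization(cohort: pd.DataFrame) -> pd.DataFrame:
    """Mean/SD of each continuous matching covariate over the full cohort."""
    stats = cohort[list(COVARIATE_COLUMNS)].agg(["mean", "std"])
    stats.loc["std"] = stats.loc["std"].replace(0.0, 1.0).fillna(1.0)
    return stats


def _check_weights(weights: dict[str, float]) -> dict[str, float]:
    if weights is None:
        return dict(DEFAULT_MATCH_WEIGHTS)
    if any(w <= 0 for w in weights.values()):
        raise ValueError("all match weights must be positive")
    return weights


def _feature_matrix(cohort: pd.DataFrame, weights: dict[str, float],
                    normalization: pd.DataFrame) -> np.ndarray:
    """Weighted normalized covariate vectors, one row per sample."""
    cols = []
    for cov in COVARIATE_COLUMNS:
        x = cohort[cov].to_numpy(dtype=float)
        if np.isnan(x).any():
            raise ValueError(f"missing covariate values in '{cov}'")
        z = (x - normalization.loc["mean", cov]) / normalization.loc["std", cov]
        cols.append(weights[cov] * z)
    sex = cohort["sex"].map({"F": 0.0, "M": 1.0}).to_numpy()
    if np.isnan(sex).any():
        raise ValueError("missing or unrecognized sex values")
    cols.append(weights["sex"] * sex)
    return np.column_stack(cols)


def covariate_distance(a, b, weights: dict[str, float] | None = None,
                       normalization: pd.DataFrame | None = None) -> float:
    """Weighted Euclidean distance between two sample records.

    ``normalization`` holds the full-cohort mean/SD of the continuous
    covariates (see :func:`cohort_normalization`); omitting it normalizes
    against the two samples alone, which is rarely what a study wants.
    """
    weights = _check_weights(weights)
    pair = pd.DataFrame([pd.Series(a), pd.Series(b)])
    if normalization is None:
        normalization = pd.DataFrame(
            {c: {"mean": 0.0, "std": 1.0} for c in COVARIATE_COLUMNS})
    feats = _feature_matrix(pair, weights, normalization)
    return float(np.linalg.norm(feats[0] - feats[1]))


def match_cases(cohort: pd.DataFrame,
                weights: dict[str, float] | None = None,
                seed: int = 0) -> list[MatchedCluster]:
    """Greedy without-replacement matching of each cancer case.

    Cases are visited in random order; for each, the nearest unused control
    in every control class (HV, NPD, NDBE) joins its cluster. Stops early if
    a control class is exhausted. Technical duplicates and HGD samples are
    excluded from matching.
    """
    weights = _check_weights(weights)
    pool = cohort[cohort["duplicate_of"].isna()]
    cases = pool[pool["diagnosis"].isin(CANCER_CLASSES)]
    if len(cases) == 0:
        raise ValueError("no cancer cases to match")
    norm = cohort_normalization(pool)
    feats = pd.DataFrame(_feature_matrix(pool, weights, norm),
                         index=pool["sample_id"].to_numpy())

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xD351]))
    case_ids = cases["sample_id"].to_numpy()
    case_order = case_ids[rng.permutation(len(case_ids))]
    available = {
        cls: set(pool.loc[pool["diagnosis"] == cls, "sample_id"])
        for cls in CONTROL_CLASSES
    }
    clusters: list[MatchedCluster] = []
    for case in case_order:
        if any(len(avail) == 0 for avail in available.values()):
            break
        controls = {}
        cf = feats.loc[case].to_numpy()
        for cls in CONTROL_CLASSES:
            ids = sorted(available[cls])  # ties -> smallest sample_id
            d = np.linalg.norm(feats.loc[ids].to_numpy() - cf, axis=1)
            best = ids[int(np.argmin(d))]
            controls[cls] = best
            available[cls].remove(best)
        clusters.append(MatchedCluster(case=case, controls=controls))
    return clusters


def random_pair_mismatch(cohort: pd.DataFrame, n_pairs: int = 100_000,
                         weights: dict[str, float] | None = None,
                         seed: int = 0) -> float:
    """Mean match distance over random distinct sample pairs.

    The study's cohort-heterogeneity diagnostic: how badly would two people
    picked at random mismatch, in the same weighted covariate space used for
    matching.
    """
    if n_pairs <= 0:
        raise ValueError("n_pairs must be positive")
    if len(cohort) < 2:
        raise ValueError("need at least two samples")
    weights = _check_weights(weights)
    norm = cohort_normalization(cohort)
    feats = _feature_matrix(cohort, weights, norm)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xA1B2]))
    n = len(cohort)
    i = rng.integers(0, n, size=n_pairs)
    j = rng.integers(0, n - 1, size=n_pairs)
    j = np.where(j >= i, j + 1, j)  # uniform over distinct pairs
    return float(np.linalg.norm(feats[i] - feats[j], axis=1).mean())


def matched_pair_mean_distance(cohort: pd.DataFrame,
                               clusters: list[MatchedCluster],
                               weights: dict[str, float] | None = None) -> float:
    """Mean case-control distance over all matched pairs."""
    weights = _check_weights(weights)
    pool = cohort[cohort["duplicate_of"].isna()]
    norm = cohort_normalization(pool)
    feats = pd.DataFrame(_feature_matrix(pool, weights, norm),
                         index=pool["sample_id"].to_numpy())
    dists = []
    for cl in clusters:
        cf = feats.loc[cl.case].to_numpy()
        for ctrl in cl.controls.values():
            dists.append(np.linalg.norm(feats.loc[ctrl].to_numpy() - cf))
    return float(np.mean(dists))


def _imbalance_objective(feats_cont: np.ndarray, is_male: np.ndarray,
                         unit_sets: list[np.ndarray]) -> float:
    """Sum of |t| (continuous) and chi-square (sex) over all unit pairs.

    ``unit_sets`` holds, per unit family (rows, plates), an integer unit id
    per sample; imbalance is accumulated over every pair of units within
    each family.
    """
    total = 0.0
    eps = 1e-12
    for unit_of in unit_sets:
        units = np.unique(unit_of)
        k = len(units)
        if k < 2:
            continue
        n = np.zeros(k)
        mean = np.zeros((k, feats_cont.shape[1]))
        var = np.zeros((k, feats_cont.shape[1]))
        males = np.zeros(k)
        for u, lab in enumerate(units):
            mask = unit_of == lab
            n[u] = mask.sum()
            sub = feats_cont[mask]
            mean[u] = sub.mean(axis=0)
            var[u] = sub.var(axis=0, ddof=1) if n[u] > 1 else 0.0
            males[u] = is_male[mask].sum()
        iu, iv = np.triu_indices(k, 1)
        se = np.sqrt(var[iu] / n[iu, None] + var[iv] / n[iv, None])
        t = np.abs(mean[iu] - mean[iv]) / (se + eps)
        total += float(t.sum())
        # 2x2 chi-square per unit pair
        a, b = males[iu], n[iu] - males[iu]
        c, d = males[iv], n[iv] - males[iv]
        nn = n[iu] + n[iv]
        chi2 = nn * (a * d - b * c) ** 2 / (
            (a + b) * (c + d) * (a + c) * (b + d) + eps)
        total += float(chi2.sum())
    return total


def optimize_plate_layout(clusters: list[MatchedCluster],
                          cohort: pd.DataFrame,
                          plates: int = 2, rows_per_plate: int = 12,
                          n_iter: int = 2000, seed: int = 0,
                          row_capacity: int | None = None) -> PlateLayout:
    """Assign samples to (plate, row) and hill-climb covariate balance.

    Matched clusters are first randomly assigned to rows (members kept
    together when capacity allows), remaining samples fill the gaps; then
    ``n_iter`` random swaps are proposed and kept only when the imbalance
    objective strictly decreases, so the acceptance trace is non-increasing.
    """
    if n_iter < 0:
        raise ValueError("n_iter must be non-negative")
    n = len(cohort)
    n_rows = plates * rows_per_plate
    if row_capacity is None:
        row_capacity = int(np.ceil(n / n_rows))
    if n_rows * row_capacity < n:
        raise ValueError("plate capacity smaller than cohort")

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x50A7]))
    sample_ids = cohort["sample_id"].to_numpy()
    pos_of = {sid: k for k, sid in enumerate(sample_ids)}

    # initial assignment: clusters to random rows, leftovers fill remaining slots
    slots_free = {r: row_capacity for r in range(n_rows)}
    unit = np.full(n, -1, dtype=int)
    row_order = rng.permutation(n_rows)
    ri = 0
    clusters = list(clusters)
    rng.shuffle(clusters)
    for cl in clusters:
        members = [m for m in cl.members() if m in pos_of]
        placed = False
        for attempt in range(n_rows):
            r = int(row_order[(ri + attempt) % n_rows])
            if slots_free[r] >= len(members):
                for m in members:
                    unit[pos_of[m]] = r
                slots_free[r] -= len(members)
                ri += attempt + 1
                placed = True
                break
        if not placed:
            break  # fall through: members placed as leftovers
    leftovers = np.flatnonzero(unit < 0)
    rng.shuffle(leftovers)
    free_slots = [r for r, c in slots_free.items() for _ in range(c)]
    rng.shuffle(free_slots)
    for k, idx in enumerate(leftovers):
        unit[idx] = free_slots[k]

    weights = dict(DEFAULT_MATCH_WEIGHTS)
    norm = cohort_normalization(cohort)
    feats = _feature_matrix(cohort, weights, norm)
    cont = feats[:, :-1]
    is_male = (cohort["sex"] == "M").to_numpy()

    def objective(u: np.ndarray) -> float:
        return _imbalance_objective(cont, is_male, [u, u // rows_per_plate])

    score = objective(unit)
    trace = [(0, score)]
    for it in range(1, n_iter + 1):
        i, j = rng.integers(0, n, size=2)
        if unit[i] == unit[j]:
            continue
        unit[i], unit[j] = unit[j], unit[i]
        new = objective(unit)
        if new < score:
            score = new
            trace.append((it, score))
        else:
            unit[i], unit[j] = unit[j], unit[i]

    assignment = pd.DataFrame({
        "sample_id": sample_ids,
        "plate": unit // rows_per_plate + 1,
        "row": unit % rows_per_plate + 1,
    })
    return PlateLayout(assignment=assignment, heterogeneity_score=score,
                       trace=trace)


def apply_layout(cohort: pd.DataFrame, layout: PlateLayout) -> pd.DataFrame:
    """Return a cohort copy with plate/row replaced by the optimized layout."""
    merged = cohort.drop(columns=["plate", "row"]).merge(
        layout.assignment, on="sample_id", how="left")
    if merged["plate"].isna().any():
        raise ValueError("layout does not cover every sample")
    merged["plate"] = merged["plate"].astype(int)
    merged["row"] = merged["row"].astype(int)
    return merged
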