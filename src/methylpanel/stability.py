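"""Resampling-robust gene selection.

A single network fit on a modest cohort is fragile: removing a handful of
samples can change the module decomposition drastically. The stability loop
repeats the whole network stage (adjacency at a fixed power, module
detection, eigengene significance, gene importance) hundreds of times, each
time leaving out a few randomly chosen samples, and averages the per-gene
importance scores across runs. Genes that score well only under one exact
cohort composition wash out.

Because module numbering is arbitrary and changes between runs, the per-run
module label vectors are clustered with k-means: genes that keep landing in
the same module (whatever it is called that run) end up in the same cluster.
Candidate gene lists are then drawn triangularly: N genes from the best
cluster, N-1 from the second best, down to 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .collapse import GeneMatrix
from .network import (DEFAULT_CUT_HEIGHT, DEFAULT_MIN_MODULE_SIZE,
                      DEFAULT_POWER, UNASSIGNED_SCORE, build_network,
                      detect_modules, gene_importance, module_eigengene,
                      module_significance)


@dataclass
class ResampleRecord:
    run: int
    removed: list[str]
    labels: np.ndarray
    scores: pd.Series
    module_p_values: dict[int, float]

    @property
    def n_modules(self) -> int:
        return int(len(set(self.labels) - {0}))


@dataclass
class CandidateList:
    k: int
    N: int
    genes: list[str]
    truncated: bool = False


def _single_pass(gm: GeneMatrix, covariates: pd.DataFrame,
                 diagnosis: pd.Series, power: int, min_size: int,
                 cut_height: float):
    net = build_network(gm, power=power)
    labels = detect_modules(net, min_size=min_size, cut_height=cut_height)
    p_values: dict[int, float] = {}
    if labels.max() > 0:
        eig, _ = module_eigengene(gm, labels)
        for mod in eig.columns:
            p_values[mod] = module_significance(
                eig[mod].to_numpy(), diagnosis.to_numpy(), covariates)
    scores = gene_importance(net, labels, p_values)
    return labels, scores, p_values


def run_resampled_networks(gm: GeneMatrix, covariates: pd.DataFrame,
                           diagnosis: pd.Series, n_runs: int = 200,
                           n_remove: int = 5, power: int = DEFAULT_POWER,
                           min_size: int = DEFAULT_MIN_MODULE_SIZE,
                           cut_height: float = DEFAULT_CUT_HEIGHT,
                           seed: int = 0):
    """Leave-``n_remove``-out network construction repeated ``n_runs`` times.

    Returns ``(records, membership, mean_scores)``: the per-run records, the
    genes x runs integer module-label matrix, and the across-run mean
    importance score per gene.
    """
    if n_runs <= 0:
        raise ValueError("n_runs must be positive")
    n_samples = gm.values.shape[1]
    if n_remove >= n_samples - 10:
        raise ValueError("n_remove too large for cohort size")
    ss = np.random.SeedSequence([int(seed), 0x5EED])
    streams = ss.spawn(n_runs)
    sample_ids = gm.sample_ids.to_numpy()
    records: list[ResampleRecord] = []
    membership = np.zeros((gm.values.shape[0], n_runs), dtype=int)
    score_sum = np.zeros(gm.values.shape[0])
    seen_removals = set()
    collisions = 0
    for r in range(n_runs):
        rng = np.random.default_rng(streams[r])
        removed = sorted(rng.choice(sample_ids, size=n_remove, replace=False)) \
            if n_remove > 0 else []
        key = tuple(removed)
        if key in seen_removals and n_remove > 0:
            collisions += 1
        seen_removals.add(key)
        keep = [s for s in sample_ids if s not in set(removed)]
        labels, scores, pvals = _single_pass(
            gm.subset_samples(keep), covariates.loc[keep],
            diagnosis.loc[keep], power, min_size, cut_height)
        records.append(ResampleRecord(run=r, removed=list(removed),
                                      labels=labels, scores=scores,
                                      module_p_values=pvals))
        membership[:, r] = labels
        score_sum += scores.to_numpy()
    if collisions:
        warnings.warn(f"{collisions} duplicate removal sets across runs")
    mm = pd.DataFrame(membership, index=gm.gene_ids.copy(),
                      columns=[f"run{r}" for r in range(n_runs)])
    mean_scores = pd.Series(score_sum / n_runs, index=gm.gene_ids.copy(),
                            name="mean_importance")
    return records, mm, mean_scores


def module_count_histogram(records: list[ResampleRecord]) -> pd.Series:
    """How many modules each resampling run produced."""
    counts = pd.Series([rec.n_modules for rec in records])
    return counts.value_counts().sort_index()


def cluster_memberships(mm: pd.DataFrame, k: int, seed: int = 0,
                        n_init: int = 10) -> pd.Series:
    """k-means on the raw per-run module-label vectors of each gene.

    Label vectors are clustered as plain integer coordinates (the study's
    literal procedure); genes with identical assignment histories always
    land in the same cluster.
    """
    X = mm.to_numpy(dtype=float)
    if not (2 <= k <= X.shape[0]):
        raise ValueError("k must lie in [2, n_genes]")
    n_distinct = np.unique(X, axis=0).shape[0]
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds the {n_distinct} distinct label vectors")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=int(seed) % (2**31))
    labels = km.fit_predict(X)
    return pd.Series(labels, index=mm.index, name="cluster")


def rank_clusters(clusters: pd.Series, mean_scores: pd.Series) -> list[int]:
    """Cluster ids ordered by the best (lowest) member mean score."""
    best = mean_scores.groupby(clusters).min()
    return list(best.sort_values(kind="mergesort").index)


def build_candidate_list(clusters: pd.Series, mean_scores: pd.Series,
                         N: int) -> CandidateList:
    """Triangular draw: N-c+1 lowest-scoring genes from the c-th cluster."""
    ranked = rank_clusters(clusters, mean_scores)
    genes: list[str] = []
    truncated = False
    for c, cluster_id in enumerate(ranked[:N], start=1):
        take = N - c + 1
        members = mean_scores[clusters == cluster_id]
        members = members.sort_values(kind="mergesort")  # ties by gene_id order
        chosen = members.index[:take].to_list()
        if len(chosen) < take:
            truncated = True
            warnings.warn(f"cluster {cluster_id} smaller than requested take")
        genes.extend(chosen)
    if len(ranked) < N:
        truncated = True
    return CandidateList(k=int(clusters.nunique()), N=N, genes=genes,
                         truncated=truncated)


def generate_candidates(mm: pd.DataFrame, mean_scores: pd.Series,
                        k_range=range(2, 21), seed: int = 0,
                        n_init: int = 10) -> list[CandidateList]:
    """All (k, N) candidate lists: k-means at each k, then N = 2..k draws.

    A k exceeding the number of distinct membership vectors (which happens
    when module recovery is very stable across runs) is skipped with a
    warning; the remaining sweep is unaffected.
    """
    candidates: list[CandidateList] = []
    n_distinct = np.unique(mm.to_numpy(dtype=float), axis=0).shape[0]
    for k in k_range:
        if k > n_distinct:
            warnings.warn(f"skipping k={k}: only {n_distinct} distinct "
                          "membership vectors")
            continue
        clusters = cluster_memberships(mm, k=k, seed=seed, n_init=n_init)
        for N in range(2, k + 1):
            cl = build_candidate_list(clusters, mean_scores, N)
            cl.k = k
            candidates.append(cl)
    return candidates
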