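"""Weighted gene-coexpression network core.

An unsigned adjacency a_ij = |cor(g_i, g_j)|^beta (soft threshold beta,
default 6) is turned into a topological overlap matrix (TOM), modules are
found by average-linkage hierarchical clustering of the TOM dissimilarity
with a static height cut, each module is summarized by its eigengene (first
principal component of the standardized member genes), and module relevance
to disease is tested by logistic regression of diagnosis on the eigengene
adjusted for age, sex and epithelial cell fraction.

A gene's importance score combines its place in its module with the module's
evidence: intramodular connectivity is normalized so the hub gene scores 1,
its reciprocal is multiplied by the module p-value, so the hub carries the
module p-value itself and peripheral genes inflate away from it. Genes not
in any module score a default of 200. Lower is more important.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.special import expit
from scipy import stats

from .collapse import GeneMatrix

UNASSIGNED_SCORE = 200.0
DEFAULT_POWER = 6
DEFAULT_MIN_MODULE_SIZE = 20
DEFAULT_CUT_HEIGHT = 0.995


@dataclass
class Network:
    adjacency: np.ndarray
    tom: np.ndarray
    power: int
    gene_ids: pd.Index


def _abs_correlation(values: np.ndarray) -> np.ndarray:
    sd = values.std(axis=1)
    if (sd == 0).any():
        warnings.warn("constant gene(s): correlations set to 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        cor = np.corrcoef(values)
    cor = np.nan_to_num(cor, nan=0.0)
    np.fill_diagonal(cor, 1.0)
    return np.abs(cor)


def build_network(gm: GeneMatrix, power: int = DEFAULT_POWER) -> Network:
    """Unsigned adjacency and topological overlap for a gene matrix."""
    if power < 1:
        raise ValueError("soft-threshold power must be >= 1")
    adj = _abs_correlation(gm.values.to_numpy(dtype=float)) ** power
    np.fill_diagonal(adj, 1.0)
    tom = topological_overlap(adj)
    return Network(adjacency=adj, tom=tom, power=power,
                   gene_ids=gm.gene_ids.copy())


def topological_overlap(adjacency: np.ndarray) -> np.ndarray:
    """TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    with the shared-neighbour sum excluding u in {i, j} and
    k_i = sum_{u != i} a_iu."""
    a0 = adjacency.copy()
    np.fill_diagonal(a0, 0.0)
    k = a0.sum(axis=1)
    shared = a0 @ a0
    num = shared + a0
    denom = np.minimum.outer(k, k) + 1.0 - a0
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = np.where(denom > 0, num / denom, 0.0)
    np.fill_diagonal(tom, 1.0)
    return tom


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10
                   ) -> tuple[float, float]:
    """Signed R^2 of the log-log degree-distribution fit.

    Connectivities are split into ``n_bins`` equal-count bins; log10 density
    is regressed on log10 mean connectivity. The R^2 is negated when the
    slope is positive (scale-free topology requires a decreasing law).
    """
    k = np.asarray(connectivity, dtype=float)
    if k.size < n_bins:
        raise ValueError("fewer genes than bins")
    order = np.sort(k)
    edges = np.quantile(order, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    idx = np.clip(np.searchsorted(edges, k, side="right") - 1,
                  0, len(edges) - 2)
    xs, ys = [], []
    total = k.size
    for b in range(len(edges) - 1):
        mask = idx == b
        if mask.sum() == 0:
            continue
        width = edges[b + 1] - edges[b]
        if width <= 0:
            continue
        dens = mask.sum() / (total * width)
        mk = k[mask].mean()
        if mk <= 0 or dens <= 0:
            continue
        xs.append(np.log10(mk))
        ys.append(np.log10(dens))
    if len(xs) < 3:
        return 0.0, 0.0
    slope, _, r, _, _ = stats.linregress(xs, ys)
    r2 = r ** 2
    return (-r2 if slope > 0 else r2), float(slope)


def pick_soft_threshold(gm: GeneMatrix,
                        candidate_powers=(1, 2, 3, 4, 5, 6, 7, 8, 9, 10),
                        r2_threshold: float = 0.8,
                        n_bins: int = 10,
                        fallback: int = DEFAULT_POWER
                        ) -> tuple[int, pd.DataFrame]:
    """Lowest power whose scale-free fit reaches the R^2 threshold.

    Falls back to the configured default (6, the study's choice) when no
    candidate reaches the threshold.
    """
    if gm.values.shape[0] < 3:
        raise ValueError("need at least 3 genes")
    abs_cor = _abs_correlation(gm.values.to_numpy(dtype=float))
    rows = []
    chosen = None
    for power in candidate_powers:
        adj = abs_cor ** power
        np.fill_diagonal(adj, 1.0)
        k = adj.sum(axis=1) - 1.0
        r2, slope = scale_free_fit(k, n_bins=n_bins)
        rows.append({"power": power, "signed_r2": r2, "slope": slope,
                     "mean_k": float(k.mean())})
        if chosen is None and r2 >= r2_threshold:
            chosen = power
    table = pd.DataFrame(rows)
    return (chosen if chosen is not None else fallback), table


def detect_modules(net: Network, min_size: int = DEFAULT_MIN_MODULE_SIZE,
                   cut_height: float = DEFAULT_CUT_HEIGHT,
                   use_tom: bool = True) -> np.ndarray:
    """Static-cut average-linkage module detection.

    Clusters the genes on dissimilarity 1 - TOM (or 1 - adjacency), cuts the
    tree at ``cut_height``, discards clusters smaller than ``min_size``
    (label 0 = unassigned) and relabels survivors 1..M by decreasing size.
    """
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    if not (0 < cut_height <= 1):
        raise ValueError("cut_height must lie in (0, 1]")
    sim = net.tom if use_tom else net.adjacency
    dis = 1.0 - sim
    np.fill_diagonal(dis, 0.0)
    dis = np.clip((dis + dis.T) / 2.0, 0.0, None)
    z = linkage(squareform(dis, checks=False), method="average")
    raw = fcluster(z, t=cut_height, criterion="distance")
    labels = np.zeros(len(raw), dtype=int)
    sizes = []
    for lab in np.unique(raw):
        members = np.flatnonzero(raw == lab)
        if len(members) >= min_size:
            sizes.append((len(members), int(members[0]), members))
    sizes.sort(key=lambda t: (-t[0], t[1]))
    for new_lab, (_, _, members) in enumerate(sizes, start=1):
        labels[members] = new_lab
    return labels


def module_eigengene(gm: GeneMatrix, labels: np.ndarray
                     ) -> tuple[pd.DataFrame, dict[int, float]]:
    """First principal component of each module's standardized genes.

    Returns (eigengenes, variance_explained); each eigengene is a unit-norm
    per-sample vector, sign-oriented to correlate positively with the module
    mean profile.
    """
    values = gm.values.to_numpy(dtype=float)
    eig = {}
    var_exp = {}
    for mod in sorted(set(labels) - {0}):
        members = np.flatnonzero(labels == mod)
        if len(members) < 2:
            raise ValueError(f"module {mod} has fewer than 2 genes")
        sub = values[members]
        sd = sub.std(axis=1)
        if (sd == 0).any():
            warnings.warn(f"zero-variance gene(s) excluded from module {mod} PC")
            sub = sub[sd > 0]
            sd = sd[sd > 0]
        z = (sub - sub.mean(axis=1, keepdims=True)) / sd[:, None]
        _, s, vt = np.linalg.svd(z, full_matrices=False)
        pc = vt[0]
        mean_profile = z.mean(axis=0)
        if np.dot(pc, mean_profile) < 0:
            pc = -pc
        eig[mod] = pc
        var_exp[mod] = float(s[0] ** 2 / (s ** 2).sum())
    frame = pd.DataFrame(eig, index=gm.sample_ids.copy())
    return frame, var_exp


def _ridge_logit_deviance(X: np.ndarray, y: np.ndarray,
                          penalty: float = 1e-4,
                          max_iter: int = 200) -> float:
    """Deviance of an IRLS logistic fit with a small L2 penalty (intercept
    unpenalized); finite even under complete separation."""
    n, p = X.shape
    beta = np.zeros(p)
    lam = np.full(p, penalty)
    lam[0] = 0.0
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        grad = X.T @ (y - mu) - lam * beta
        hess = (X * w[:, None]).T @ X + np.diag(lam)
        step = np.linalg.solve(hess, grad)
        if np.max(np.abs(step)) > 10:     # dampen early huge steps
            step *= 10 / np.max(np.abs(step))
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    eta = X @ beta
    loglik = float(np.sum(y * eta - np.log1p(np.exp(np.clip(eta, None, 500)))))
    return -2.0 * loglik


def _separation_fallback_p(X: np.ndarray, y: np.ndarray,
                           penalty: float = 1e-4) -> float:
    """Ridge-penalized likelihood-ratio p-value for the eigengene (column 1).

    Under (quasi-)complete separation the Wald statistic collapses
    (Hauck-Donner effect) even after ridge stabilization, so the fallback
    tests the eigengene by the deviance drop it produces instead.
    """
    dev_full = _ridge_logit_deviance(X, y, penalty)
    dev_null = _ridge_logit_deviance(np.delete(X, 1, axis=1), y, penalty)
    lr = max(0.0, dev_null - dev_full)
    return float(stats.chi2.sf(lr, df=1))


def module_significance(eigengene: np.ndarray, diagnosis: np.ndarray,
                        covariates: pd.DataFrame) -> float:
    """Wald p-value of the eigengene in an adjusted logistic regression.

    Diagnosis (binary cancer indicator) is regressed on the eigengene plus
    age, sex and epithelial fraction; the returned p-value is for the
    eigengene coefficient, i.e. the module must carry disease signal beyond
    those covariates. Separated or non-converged fits fall back to a
    ridge-penalized (1e-4) likelihood-ratio test, which keeps its power
    where the Wald statistic degenerates.
    """
    import statsmodels.api as sm

    y = np.asarray(diagnosis, dtype=float)
    if len(set(y)) < 2:
        raise ValueError("both outcome classes must be present")
    covs = covariates.copy()
    if "sex" in covs and covs["sex"].dtype == object:
        covs["sex"] = covs["sex"].map({"F": 0.0, "M": 1.0})
    X = np.column_stack([np.ones_like(y), np.asarray(eigengene, dtype=float),
                         covs.to_numpy(dtype=float)])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        p = float(fit.pvalues[1])
        unstable = (not np.isfinite(p) or not np.isfinite(fit.bse[1])
                    or fit.bse[1] > 1e2 or abs(fit.params[1]) > 30
                    or not fit.mle_retvals.get("converged", True))
        if unstable:
            raise ValueError("unstable fit")
        return p
    except Exception:
        warnings.warn("separation or non-convergence: ridge-penalized refit")
        return _separation_fallback_p(X, y)


def gene_importance(net: Network, labels: np.ndarray,
                    p_values: dict[int, float]) -> pd.Series:
    """Module p-value divided by hub-normalized intramodular connectivity.

    The hub gene of module m scores exactly p_m; other members score
    p_m / (k_i / max_j k_j) > p_m; unassigned genes score 200.
    """
    modules = sorted(set(labels) - {0})
    missing = [m for m in modules if m not in p_values]
    if missing:
        raise ValueError(f"missing p-values for modules {missing}")
    scores = np.full(len(labels), UNASSIGNED_SCORE, dtype=float)
    a0 = net.adjacency.copy()
    np.fill_diagonal(a0, 0.0)
    for mod in modules:
        members = np.flatnonzero(labels == mod)
        k = a0[np.ix_(members, members)].sum(axis=1)
        kmax = k.max()
        if kmax == 0:
            warnings.warn(f"module {mod} has zero connectivity; members set to 200")
            continue
        scores[members] = p_values[mod] / (k / kmax)
    return pd.Series(scores, index=net.gene_ids, name="importance")
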