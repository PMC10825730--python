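"""Cell-fraction estimation, row-batch residualization, SVD diagnostics.

Saliva is a mixture of epithelial and immune cells (plus a trace fibroblast
component); the epithelial fraction is estimated per sample by constrained
least squares of marker-probe beta values against cell-type reference
profiles (non-negative fractions summing to one).

Array batch structure (plate rows, globally unique across plates) is removed
by fitting, per probe, an ordinary least-squares model on row-batch
indicators and keeping the residuals; every per-batch residual mean is zero
to machine precision, so no linear summary of the residual matrix — in
particular no principal component — can retain any row-batch association.
The SVD diagnostic table makes that auditable: ANOVA p-values of the leading
components against categorical covariates, correlation-test p-values against
continuous ones.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import ProbeMatrix


def estimate_cell_fractions(matrix: ProbeMatrix,
                            reference: pd.DataFrame) -> pd.DataFrame:
    """Per-sample cell-type fractions by simplex-constrained least squares.

    ``reference`` is a marker-probes x cell-types table of reference beta
    profiles; its probes must be present in the matrix. For each sample the
    fraction vector f minimizes ||R f - y||^2 subject to f >= 0 and
    sum(f) = 1, solved exactly by active-set enumeration (the KKT system of
    every support set is tiny).
    """
    missing = reference.index.difference(matrix.probe_ids)
    if len(missing) > 0:
        raise ValueError("reference probes missing from matrix")
    R = reference.to_numpy(dtype=float)
    if np.linalg.matrix_rank(R) < R.shape[1]:
        raise ValueError("rank-deficient reference profile matrix")
    Y = matrix.values.loc[reference.index].to_numpy(dtype=float)
    k = R.shape[1]
    supports = [s for r in range(1, k + 1)
                for s in itertools.combinations(range(k), r)]
    out = np.zeros((Y.shape[1], k))
    for j in range(Y.shape[1]):
        y = Y[:, j]
        best, best_rss = None, np.inf
        for sup in supports:
            Rs = R[:, sup]
            # KKT of min ||Rs f - y||^2 s.t. 1'f = 1
            G = Rs.T @ Rs
            m = len(sup)
            kkt = np.zeros((m + 1, m + 1))
            kkt[:m, :m] = G
            kkt[:m, m] = 1.0
            kkt[m, :m] = 1.0
            rhs = np.concatenate([Rs.T @ y, [1.0]])
            try:
                sol = np.linalg.solve(kkt, rhs)
            except np.linalg.LinAlgError:
                continue
            f = sol[:m]
            if (f < -1e-9).any():
                continue
            rss = float(((Rs @ f - y) ** 2).sum())
            if rss < best_rss - 1e-12:
                best_rss = rss
                best = (sup, np.clip(f, 0.0, None))
        sup, f = best
        full = np.zeros(k)
        full[list(sup)] = f / f.sum()
        out[j] = full
    return pd.DataFrame(out, index=matrix.sample_ids.copy(),
                        columns=reference.columns)


def batch_residualize(matrix: ProbeMatrix,
                      row_batch: pd.Series) -> ProbeMatrix:
    """Residuals of a per-probe OLS fit on row-batch indicators.

    With a categorical-only design this is exactly per-batch mean centering
    of every probe. Returns a matrix on the ``residual`` scale.
    """
    batch = row_batch.loc[matrix.sample_ids]
    levels = batch.unique()
    if len(levels) < 2:
        warnings.warn("single batch level: residuals reduce to probe centering")
    vals = matrix.values.to_numpy(dtype=float).copy()
    codes = pd.Categorical(batch).codes
    for lev in range(codes.max() + 1):
        cols = codes == lev
        vals[:, cols] -= vals[:, cols].mean(axis=1, keepdims=True)
    frame = pd.DataFrame(vals, index=matrix.probe_ids.copy(),
                         columns=matrix.sample_ids.copy())
    return ProbeMatrix(frame, scale="residual",
                       control_intensity=matrix.control_intensity)


def batch_intercepts(matrix: ProbeMatrix, row_batch: pd.Series) -> pd.DataFrame:
    """Per-probe per-batch model means (kept so a deployment baseline can be
    reconstructed for single new arrays; not re-applied by the pipeline)."""
    batch = row_batch.loc[matrix.sample_ids]
    return matrix.values.T.groupby(batch.to_numpy()).mean().T


def svd_scores(matrix: ProbeMatrix, n_components: int = 10) -> pd.DataFrame:
    """Per-sample scores of the leading components of the probe-centered SVD."""
    vals = matrix.values.to_numpy(dtype=float)
    centered = vals - vals.mean(axis=1, keepdims=True)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    n_components = min(n_components, vt.shape[0])
    return pd.DataFrame(vt[:n_components].T, index=matrix.sample_ids.copy(),
                        columns=[f"PC{i + 1}" for i in range(n_components)])


def svd_diagnostics(matrix: ProbeMatrix, covariates: pd.DataFrame,
                    n_components: int = 10,
                    categorical: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Association p-values of leading SVD components vs. study covariates.

    Categorical covariates (object/category/bool dtype, or named in
    ``categorical``) are tested by one-way ANOVA of the component scores
    across levels; continuous ones by the Pearson correlation t-test.
    Constant covariates record p = 1.
    """
    if matrix.values.shape[1] < 10:
        raise ValueError("need at least 10 samples for SVD diagnostics")
    scores = svd_scores(matrix, n_components)
    covs = covariates.loc[scores.index]
    out = pd.DataFrame(index=scores.columns, columns=covs.columns, dtype=float)
    for cov in covs.columns:
        x = covs[cov]
        is_cat = (categorical is not None and cov in categorical) or \
            x.dtype == object or isinstance(x.dtype, pd.CategoricalDtype) or \
            x.dtype == bool
        for comp in scores.columns:
            s = scores[comp].to_numpy()
            if x.nunique() < 2:
                out.loc[comp, cov] = 1.0
                continue
            if is_cat:
                groups = [s[(x == lev).to_numpy()] for lev in x.unique()]
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    stat, p = stats.f_oneway(*groups)
                out.loc[comp, cov] = 1.0 if np.isnan(p) else float(p)
            else:
                _, p = stats.pearsonr(s, x.to_numpy(dtype=float))
                out.loc[comp, cov] = float(p)
    return out
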