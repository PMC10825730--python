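"""Array quality control: KS reproducibility, duplicate resolution, filters.

Reproducibility of technical replicate arrays is assessed with the
Kolmogorov-Smirnov distance between beta-value distributions: each array is
compared with a leave-one-out "average array" of all other samples, and of
each duplicate pair the member closer to the average is kept. Arrays whose
distance to the average exceeds 0.6 are flagged as suspect but not removed
(stringent KS-based discarding would remove good arrays along with bad).

Two hard removal rules are applied: simulated bisulfite-conversion control
intensity below 2000, and an M-value density whose global peak falls outside
a window around -5 (a hallmark of systematic array failure).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde, ks_2samp

from .simulate import ProbeMatrix

BISULFITE_INTENSITY_THRESHOLD = 2000.0
KS_SUSPECT_THRESHOLD = 0.6
M_PEAK_WINDOW = (-6.5, -3.5)
_BETA_CLAMP = 1e-6


def m_values(beta: np.ndarray | pd.DataFrame):
    """M = log2(beta / (1 - beta)) with beta clamped away from {0, 1}."""
    b = np.clip(beta, _BETA_CLAMP, 1.0 - _BETA_CLAMP)
    return np.log2(b / (1.0 - b))


def ks_distance(sample_a: np.ndarray, sample_b: np.ndarray) -> float:
    """Two-sample KS statistic between two beta-value vectors."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("cannot compute KS distance of an empty vector")
    return float(ks_2samp(a, b, method="asymp").statistic)


def average_array(matrix: ProbeMatrix, exclude: str | None = None) -> pd.Series:
    """Per-probe mean across samples, optionally excluding one sample."""
    vals = matrix.values
    if exclude is not None:
        vals = vals.drop(columns=exclude)
    if vals.shape[1] < 1 or matrix.values.shape[1] < 2:
        raise ValueError("average array needs at least two samples")
    return vals.mean(axis=1)


def ks_to_average(matrix: ProbeMatrix) -> pd.Series:
    """Leave-one-out KS distance of every sample to the average array."""
    vals = matrix.values.to_numpy()
    n = vals.shape[1]
    if n < 2:
        raise ValueError("need at least two samples")
    total = vals.sum(axis=1)
    out = {}
    for j, sid in enumerate(matrix.sample_ids):
        avg = (total - vals[:, j]) / (n - 1)
        out[sid] = ks_distance(vals[:, j], avg)
    return pd.Series(out, name="ks_to_mean")


def _empty_report(matrix: ProbeMatrix) -> pd.DataFrame:
    report = pd.DataFrame(index=matrix.sample_ids.copy())
    report.index.name = "sample_id"
    report["ks_to_mean"] = np.nan
    report["control_intensity"] = (
        matrix.control_intensity.reindex(report.index)
        if matrix.control_intensity is not None else np.nan)
    report["m_density_peak"] = np.nan
    report["removed"] = False
    report["removal_reason"] = "none"
    report["ks_suspect"] = False
    return report


def resolve_duplicates(matrix: ProbeMatrix,
                       pairs: list[tuple[str, str]],
                       suspect_threshold: float = KS_SUSPECT_THRESHOLD
                       ) -> tuple[ProbeMatrix, pd.DataFrame]:
    """Keep, per duplicate pair, the member nearer the average array.

    The losing member is removed with reason ``duplicate_loser``; ties keep
    the lexicographically smaller sample_id. Samples whose distance to the
    average exceeds ``suspect_threshold`` are flagged (advisory only).
    """
    for a, b in pairs:
        if a not in matrix.sample_ids or b not in matrix.sample_ids:
            raise ValueError(f"duplicate pair ({a}, {b}) not fully present")
    report = _empty_report(matrix)
    ks = ks_to_average(matrix)
    report["ks_to_mean"] = ks
    report["ks_suspect"] = ks > suspect_threshold
    losers = []
    for a, b in pairs:
        if ks[a] < ks[b] or (ks[a] == ks[b] and a < b):
            losers.append(b)
        else:
            losers.append(a)
    report.loc[losers, "removed"] = True
    report.loc[losers, "removal_reason"] = "duplicate_loser"
    kept = [s for s in matrix.sample_ids if s not in set(losers)]
    return matrix.subset_samples(kept), report


def m_density_peak(beta: np.ndarray, grid: np.ndarray | None = None) -> float:
    """Location of the global maximum of the M-value kernel density.

    Gaussian kernel with Silverman's bandwidth, evaluated on a fixed grid.
    """
    m = m_values(np.asarray(beta, dtype=float))
    if grid is None:
        grid = np.linspace(-12.0, 12.0, 481)
    kde = gaussian_kde(m, bw_method="silverman")
    dens = kde(grid)
    return float(grid[int(np.argmax(dens))])


def qc_filter(matrix: ProbeMatrix,
              intensity_threshold: float = BISULFITE_INTENSITY_THRESHOLD,
              m_peak_window: tuple[float, float] = M_PEAK_WINDOW
              ) -> tuple[ProbeMatrix, pd.DataFrame]:
    """Remove bisulfite-control failures and M-density-peak outliers.

    A sample is removed if its control intensity is below the threshold
    (reason ``bisulfite``, applied regardless of any other measure), or if
    the global peak of its M-value density lies outside ``m_peak_window``
    (reason ``density_outlier``).
    """
    report = _empty_report(matrix)
    if matrix.control_intensity is None:
        raise ValueError("qc_filter requires per-sample control intensities")
    vals = matrix.values
    lo, hi = m_peak_window
    for sid in matrix.sample_ids:
        peak = m_density_peak(vals[sid].to_numpy())
        report.loc[sid, "m_density_peak"] = peak
        if matrix.control_intensity[sid] < intensity_threshold:
            report.loc[sid, "removed"] = True
            report.loc[sid, "removal_reason"] = "bisulfite"
        elif not (lo <= peak <= hi):
            report.loc[sid, "removed"] = True
            report.loc[sid, "removal_reason"] = "density_outlier"
    kept = report.index[~report["removed"]].to_list()
    return matrix.subset_samples(kept), report


def duplicate_pairs_from_cohort(cohort: pd.DataFrame,
                                sample_ids=None) -> list[tuple[str, str]]:
    """(original, duplicate) links present in a cohort sheet."""
    dups = cohort[cohort["duplicate_of"].notna()]
    pairs = [(row["duplicate_of"], row["sample_id"])
             for _, row in dups.iterrows()]
    if sample_ids is not None:
        present = set(sample_ids)
        pairs = [(a, b) for a, b in pairs if a in present and b in present]
    return pairs
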