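"""Collapse the probe matrix to one representative probe per gene (MaxMean).

Several probes usually map to one gene; network analysis needs a single row
per gene. The MaxMean policy keeps, for each gene, the probe with the
highest mean across all samples (ties broken by the smaller probe_id);
probes without a gene mapping are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .simulate import ProbeMatrix


@dataclass
class GeneMatrix:
    """Genes x samples matrix after probe collapse."""

    values: pd.DataFrame
    chosen_probe: pd.Series  # gene_id -> probe_id

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def subset_samples(self, sample_ids) -> "GeneMatrix":
        return GeneMatrix(self.values.loc[:, sample_ids], self.chosen_probe)


def collapse_max_mean(matrix: ProbeMatrix,
                      annotation: pd.DataFrame) -> GeneMatrix:
    """One row per gene: the member probe with the maximal across-sample mean.

    ``annotation`` maps probe_id -> gene_symbol; probes absent from it are
    dropped. Values of the chosen probe are carried over unchanged.
    """
    if annotation is None or len(annotation) == 0:
        raise ValueError("empty probe-gene annotation")
    ann = annotation[annotation["probe_id"].isin(matrix.probe_ids)]
    if len(ann) == 0:
        raise ValueError("annotation covers no probe in the matrix")
    means = matrix.values.mean(axis=1)
    ann = ann.assign(mean=means.loc[ann["probe_id"]].to_numpy())
    # stable argmax with probe_id tie-break: best mean first, then smallest id
    ann = ann.sort_values(["gene_symbol", "mean", "probe_id"],
                          ascending=[True, False, True], kind="mergesort")
    best = ann.drop_duplicates("gene_symbol", keep="first")
    chosen = pd.Series(best["probe_id"].to_numpy(),
                       index=best["gene_symbol"].to_numpy(),
                       name="chosen_probe").sort_index()
    values = matrix.values.loc[chosen.to_numpy()].copy()
    values.index = pd.Index(chosen.index, name="gene_id")
    return GeneMatrix(values=values, chosen_probe=chosen)
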