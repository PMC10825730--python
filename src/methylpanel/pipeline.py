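"""End-to-end pipeline: simulate -> design -> qc -> preprocess -> collapse
-> resample-select -> classify, with a serializable configuration and a
manifest for reproducibility.

One master seed spawns a named substream per stage, so re-running any stage
with the same configuration reproduces it bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, asdict, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify, collapse, design, preprocess, qc, stability
from .simulate import (DEFAULT_GROUP_SIZES, DEFAULT_SEX_RATIO, TruthParams,
                       generate_cohort, generate_methylation)

STAGES = ("simulate", "design", "qc", "preprocess", "collapse",
          "select", "classify")


@dataclass
class PipelineConfig:
    """All stage parameters with study-emulating defaults."""

    seed: int = 0
    # cohort
    group_sizes: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    sex_ratio: float = DEFAULT_SEX_RATIO
    n_duplicates: int = 10
    # methylation generator
    n_genes: int = 1000
    n_modules: int = 5
    module_size: int = 30
    disease_effect: float = 0.8
    module_cor: float = 0.6
    batch_sd: float = 0.4
    n_bisulfite_failures: int = 0
    n_density_failures: int = 0
    # plate design
    plates: int = 2
    rows_per_plate: int = 12
    design_iterations: int = 500
    # network / resampling
    power: int = 6
    n_runs: int = 200
    n_remove: int = 5
    min_module_size: int = 20
    cut_height: float = 0.995
    # candidate generation
    k_min: int = 2
    k_max: int = 20
    # classification
    split_fractions: tuple = (0.64, 0.16, 0.20)
    rf_n_estimators: int = 100
    n_boot_winner: int = 2000
    cost_weights: tuple = (1, 2, 5, 10, 20, 50)

    def truth_params(self) -> TruthParams:
        return TruthParams(
            n_genes=self.n_genes, n_modules=self.n_modules,
            module_size=self.module_size, disease_effect=self.disease_effect,
            module_cor=self.module_cor, batch_sd=self.batch_sd,
            n_bisulfite_failures=self.n_bisulfite_failures,
            n_density_failures=self.n_density_failures)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(asdict(self))), fh,
                           sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        for name in ("split_fractions", "cost_weights"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    config: PipelineConfig
    cohort: pd.DataFrame
    truth: object
    qc_report: pd.DataFrame
    cell_fractions: pd.DataFrame
    diagnostics: pd.DataFrame
    gene_matrix: object
    split: pd.Series
    mean_scores: pd.Series
    membership: pd.DataFrame
    records: list
    evaluations: list
    winner: object
    ranking: pd.DataFrame
    sweep: pd.DataFrame
    manifest: dict


def _stage_seed(master: int, stage: str) -> int:
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def run_all(config: PipelineConfig | None = None,
            out_dir: str | Path | None = None) -> PipelineResult:
    """Execute every stage and (optionally) persist all outputs + manifest."""
    cfg = config or PipelineConfig()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}

    def save(df, name: str, **kw):
        if out is None:
            return
        path = out / name
        sep = "\t" if name.endswith(".tsv") else ","
        df.to_csv(path, sep=sep, **kw)
        outputs[name] = str(path)

    completed = []

    # -- simulate ----------------------------------------------------------
    cohort = generate_cohort(cfg.group_sizes, cfg.sex_ratio,
                             n_duplicates=cfg.n_duplicates,
                             seed=_stage_seed(cfg.seed, "simulate"))
    completed.append("simulate")

    # -- design ------------------------------------------------------------
    dseed = _stage_seed(cfg.seed, "design")
    clusters = design.match_cases(cohort, seed=dseed)
    layout = design.optimize_plate_layout(
        clusters, cohort, plates=cfg.plates,
        rows_per_plate=cfg.rows_per_plate,
        n_iter=cfg.design_iterations, seed=dseed)
    cohort = design.apply_layout(cohort, layout)
    save(layout.assignment, "plate_layout.csv", index=False)
    matched_mean = design.matched_pair_mean_distance(cohort, clusters)
    random_mean = design.random_pair_mismatch(
        cohort, n_pairs=20_000, seed=dseed)
    completed.append("design")

    matrix, truth, annotation = generate_methylation(
        cohort, cfg.truth_params(), seed=_stage_seed(cfg.seed, "simulate"))
    save(cohort, "sample_sheet.csv", index=False)
    save(annotation, "annotation.csv", index=False)
    if out is not None:
        truth.to_json(out / "ground_truth.json")
        outputs["ground_truth.json"] = str(out / "ground_truth.json")

    # -- qc ----------------------------------------------------------------
    pairs = qc.duplicate_pairs_from_cohort(cohort, matrix.sample_ids)
    matrix2, dup_report = qc.resolve_duplicates(matrix, pairs)
    matrix3, filter_report = qc.qc_filter(matrix2)
    qc_report = dup_report.copy()
    keep_cols = filter_report.index
    qc_report.loc[keep_cols, "m_density_peak"] = filter_report["m_density_peak"]
    newly = filter_report.index[filter_report["removed"]]
    qc_report.loc[newly, "removed"] = True
    qc_report.loc[newly, "removal_reason"] = \
        filter_report.loc[newly, "removal_reason"]
    save(qc_report, "qc_report.csv")
    cohort_kept = cohort[cohort["sample_id"].isin(matrix3.sample_ids)].copy()
    completed.append("qc")

    # -- preprocess --------------------------------------------------------
    fractions = preprocess.estimate_cell_fractions(
        matrix3, truth.marker_reference)
    residual = preprocess.batch_residualize(
        matrix3, _row_batch(cohort_kept, cfg.rows_per_plate))
    covs = _diagnostic_covariates(cohort_kept, fractions, cfg.rows_per_plate)
    diagnostics = preprocess.svd_diagnostics(
        residual, covs, categorical=("plate", "row_batch", "diagnosis"))
    save(fractions, "cell_fractions.csv")
    save(diagnostics, "svd_diagnostics.csv")
    completed.append("preprocess")

    # -- collapse ----------------------------------------------------------
    gm = collapse.collapse_max_mean(residual, annotation)
    save(gm.chosen_probe.rename_axis("gene_id").to_frame(), "chosen_probes.csv")
    completed.append("collapse")

    # -- select (resampled networks + clustering + candidates) -------------
    sseed = _stage_seed(cfg.seed, "select")
    split = classify.split_cohort(cohort_kept, cfg.split_fractions,
                                  seed=_stage_seed(cfg.seed, "classify"))
    model_covs = _model_covariates(cohort_kept, fractions)
    diagnosis = pd.Series(cohort_kept["diagnosis"].to_numpy(),
                          index=cohort_kept["sample_id"].to_numpy())
    disc_ids = split.index[split == "discovery"]
    gm_disc = gm.subset_samples(disc_ids)
    records, mm, mean_scores = stability.run_resampled_networks(
        gm_disc, model_covs.loc[disc_ids],
        classify.binarize_diagnosis(diagnosis.loc[disc_ids]),
        n_runs=cfg.n_runs, n_remove=cfg.n_remove, power=cfg.power,
        min_size=cfg.min_module_size, cut_height=cfg.cut_height, seed=sseed)
    candidates = stability.generate_candidates(
        mm, mean_scores, k_range=range(cfg.k_min, cfg.k_max + 1), seed=sseed)
    summary = pd.DataFrame({
        "mean_importance": mean_scores,
        "n_assigned": (mm.to_numpy() > 0).sum(axis=1),
    })
    save(summary, "gene_scores.tsv")
    if out is not None:
        payload = [{"k": c.k, "N": c.N, "genes": c.genes,
                    "truncated": c.truncated} for c in candidates]
        (out / "candidates.json").write_text(json.dumps(payload, indent=1))
        outputs["candidates.json"] = str(out / "candidates.json")
    completed.append("select")

    # -- classify ----------------------------------------------------------
    cseed = _stage_seed(cfg.seed, "classify")
    rf_params = {"n_estimators": cfg.rf_n_estimators}
    evaluations = []
    for i, cand in enumerate(candidates):
        evaluations.append(classify.train_and_evaluate(
            cand, gm, model_covs, diagnosis, split, rf_params=rf_params,
            n_boot=0, seed=cseed + i))
    winner, ranking = classify.rank_classifiers(evaluations)
    # re-evaluate the winner with bootstrap confidence intervals (same seed
    # as its sweep evaluation, so the model and point metrics are identical)
    win_idx = evaluations.index(winner)
    winner = classify.train_and_evaluate(
        winner.candidate, gm, model_covs, diagnosis, split,
        rf_params=rf_params, n_boot=cfg.n_boot_winner, seed=cseed + win_idx)
    hgd_ids = split.index[split == "hgd_holdout"]
    probs = dict(winner.probabilities)
    if len(hgd_ids):
        p_hgd = winner.model.predict_proba(
            winner.features.loc[hgd_ids].to_numpy())[:, 1]
        probs["hgd_holdout"] = (np.ones(len(hgd_ids), dtype=int), p_hgd)
    sweep = classify.cost_sweep(probs, weights=cfg.cost_weights)
    save(ranking, "candidate_ranking.csv", index=False)
    save(sweep, "cost_sweep.csv", index=False)
    if out is not None:
        (out / "winner_metrics.json").write_text(json.dumps({
            "k": winner.candidate.k, "N": winner.candidate.N,
            "genes": winner.candidate.genes,
            "metrics": winner.metrics,
            "matched_pair_mean_distance": matched_mean,
            "random_pair_mismatch": random_mean,
        }, indent=1, default=float))
        outputs["winner_metrics.json"] = str(out / "winner_metrics.json")
    completed.append("classify")

    manifest = {
        "config": asdict(cfg), "config_digest": cfg.digest(),
        "seed": cfg.seed, "stages": completed, "outputs": sorted(outputs),
    }
    if out is not None:
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=1, default=list))

    return PipelineResult(
        config=cfg, cohort=cohort_kept, truth=truth, qc_report=qc_report,
        cell_fractions=fractions, diagnostics=diagnostics, gene_matrix=gm,
        split=split, mean_scores=mean_scores, membership=mm, records=records,
        evaluations=evaluations, winner=winner, ranking=ranking, sweep=sweep,
        manifest=manifest)


def _row_batch(cohort: pd.DataFrame, rows_per_plate: int) -> pd.Series:
    """Globally unique row id (rows nested in plates)."""
    rb = (cohort["plate"] - 1) * rows_per_plate + cohort["row"]
    return pd.Series(rb.to_numpy(), index=cohort["sample_id"].to_numpy(),
                     name="row_batch")


def _diagnostic_covariates(cohort: pd.DataFrame, fractions: pd.DataFrame,
                           rows_per_plate: int) -> pd.DataFrame:
    idx = cohort["sample_id"].to_numpy()
    return pd.DataFrame({
        "plate": cohort["plate"].astype(str).to_numpy(),
        "row_batch": _row_batch(cohort, rows_per_plate).astype(str).to_numpy(),
        "age": cohort["age"].to_numpy(),
        "sex": cohort["sex"].to_numpy(),
        "diagnosis": cohort["diagnosis"].to_numpy(),
        "epithelial": fractions.loc[idx, "epithelial"].to_numpy(),
    }, index=idx)


def _model_covariates(cohort: pd.DataFrame,
                      fractions: pd.DataFrame) -> pd.DataFrame:
    idx = cohort["sample_id"].to_numpy()
    return pd.DataFrame({
        "age": cohort["age"].to_numpy(),
        "sex": cohort["sex"].to_numpy(),
        "epithelial": fractions.loc[idx, "epithelial"].to_numpy(),
    }, index=idx)
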