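"""Synthetic saliva-methylation cohorts with known ground truth.

The generator emulates the structure a saliva EPIC-array case-control study
hands to the analysis pipeline: a cohort of healthy volunteers (HV),
endoscopy-negative subjects (NPD), nondysplastic Barrett's esophagus (NDBE),
high-grade dysplasia (HGD, held out), intramucosal (IMC) and invasive
esophageal adenocarcinoma, with lifestyle covariates; a beta-value probe
matrix with planted correlated gene modules (one or more disease-associated),
covariate-linked drift, epithelial/immune cell mixing on marker probes,
additive plate/row batch effects on the logit scale, and technical duplicate
pairs with pair-specific replication noise.

Every quantity planted here is recorded in :class:`GroundTruth` so the
downstream stages (QC, batch residualization, network module detection,
importance scoring, classification) can be verified end to end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import truncnorm

DIAGNOSES = ("HV", "NPD", "NDBE", "HGD", "IMC", "INVASIVE")
CANCER_CLASSES = frozenset({"IMC", "INVASIVE"})
CONTROL_CLASSES = ("HV", "NPD", "NDBE")

#: study-default class sizes: 74 HV + 42 NPD + 52 NDBE + 28 IMC + 60 invasive
#: = 256 analysis samples, plus 9 HGD held out for independent testing.
DEFAULT_GROUP_SIZES = {
    "HV": 74, "NPD": 42, "NDBE": 52, "HGD": 9, "IMC": 28, "INVASIVE": 60,
}

#: cohort-wide male:female ratio of the study population
DEFAULT_SEX_RATIO = 2.52

# (mean, sd) of truncated-normal covariate distributions; cancer groups are
# older and heavier consumers of tobacco/PPI on average, HGD sits between.
_COV_PARAMS = {
    "cancer": {"age": (70.9, 8.8), "bmi": (28.2, 4.83), "ppi": (1.72, 2.73),
               "smoking": (7.43, 14.4), "alcohol": (12.07, 10.0),
               "heartburn": (1.14, 2.3)},
    "control": {"age": (63.2, 13.4), "bmi": (26.8, 4.67), "ppi": (1.24, 1.83),
                "smoking": (3.42, 7.98), "alcohol": (11.46, 9.5),
                "heartburn": (1.24, 2.3)},
    "hgd": {"age": (66.0, 10.0), "bmi": (28.0, 4.8), "ppi": (1.7, 2.5),
            "smoking": (7.5, 12.0), "alcohol": (12.0, 10.0),
            "heartburn": (1.3, 2.4)},
}

COVARIATE_COLUMNS = ("age", "bmi", "ppi", "smoking", "alcohol", "heartburn")

_BETA_EPS = 1e-6

#: empirical correlation shrinkage of the logit->beta transform for signals
#: of the magnitude this generator plants (measured once on the default
#: baseline mixture; see the methods note)
_SQUASH_ATTENUATION = 0.87


def _clamp_beta(values: np.ndarray) -> np.ndarray:
    return np.clip(values, _BETA_EPS, 1.0 - _BETA_EPS)


@dataclass
class ProbeMatrix:
    """Probes x samples methylation matrix.

    values: DataFrame indexed by probe_id with sample_id columns.
    scale: 'beta' (values in [0,1]), 'm' (logit2) or 'residual'.
    control_intensity: per-sample simulated bisulfite-control intensity.
    """

    values: pd.DataFrame
    scale: str = "beta"
    control_intensity: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise ValueError("probe_ids and sample_ids must be unique")
        if self.values.isna().any().any():
            raise ValueError("missing values in probe matrix")
        if self.scale == "beta":
            vals = self.values.to_numpy()
            if vals.min() < 0 or vals.max() > 1:
                raise ValueError("beta values must lie in [0, 1]")

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def subset_samples(self, sample_ids) -> "ProbeMatrix":
        ci = None
        if self.control_intensity is not None:
            ci = self.control_intensity.loc[sample_ids]
        return ProbeMatrix(self.values.loc[:, sample_ids], self.scale, ci)


@dataclass
class GroundTruth:
    """Planted structure behind a synthetic probe matrix."""

    module_assignment_true: dict[str, int]
    disease_modules: set[int]
    disease_effect: float
    batch_effects: dict[str, float]       # "block|plate|row" -> logit shift
    duplicate_noise: dict[str, float]     # duplicate sample_id -> noise SD
    covariate_loadings: dict[str, dict[str, float]]
    marker_reference: pd.DataFrame | None = None  # marker probes x cell types

    def disease_genes(self) -> list[str]:
        return sorted(g for g, m in self.module_assignment_true.items()
                      if m in self.disease_modules)

    def to_json(self, path) -> None:
        payload = asdict(self)
        payload["disease_modules"] = sorted(self.disease_modules)
        ref = payload.pop("marker_reference")
        if self.marker_reference is not None:
            payload["marker_reference"] = self.marker_reference.to_dict()
        else:
            payload["marker_reference"] = None
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


@dataclass
class TruthParams:
    """Knobs of the methylation generator (study-emulating defaults)."""

    n_genes: int = 1000
    n_modules: int = 5
    module_size: int = 30
    disease_modules: tuple[int, ...] = (1,)
    disease_effect: float = 0.8          # standardized latent shift in cancer
    module_cor: float = 0.6              # target observed mean |cor| within a module
    max_probes_per_gene: int = 3
    logit_scale: float = 0.5             # logit units per latent SD
    probe_noise_sd: float = 0.2          # logit-scale iid probe noise
    batch_sd: float = 0.4                # SD of per-(block,plate,row) shifts
    probe_block_size: int = 50
    n_age_genes: int = 50
    age_loading: float = 0.3
    n_smoking_genes: int = 30
    smoking_loading: float = 0.2
    n_marker_probes: int = 60
    marker_noise_sd: float = 0.02
    fibroblast_fraction: float = 0.005
    duplicate_noise_sds: tuple[float, ...] = (0.1, 0.1, 0.1, 0.1, 0.8, 0.8, 1.2, 1.2, 1.6, 1.6)
    control_intensity_mean: float = 8000.0
    control_intensity_sd: float = 1500.0
    n_bisulfite_failures: int = 0
    n_density_failures: int = 0


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lower: float, size: int) -> np.ndarray:
    a = (lower - mean) / sd
    return truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size,
                         random_state=rng)


def generate_cohort(n_per_group: dict[str, int] | None = None,
                    sex_ratio: float = DEFAULT_SEX_RATIO,
                    n_duplicates: int = 0,
                    seed: int = 0) -> pd.DataFrame:
    """Draw a synthetic cohort sample sheet.

    Returns a DataFrame with one row per array: sample_id, diagnosis, age,
    sex, bmi, smoking, alcohol, ppi, heartburn, plate, row, duplicate_of and
    the latent epithelial cell fraction. Technical duplicates (if requested)
    copy the phenotype of their source sample and set ``duplicate_of``.
    Plate/row receive a provisional round-robin assignment; the study-design
    stage reassigns them.
    """
    if n_per_group is None:
        n_per_group = dict(DEFAULT_GROUP_SIZES)
    if any(n < 0 for n in n_per_group.values()):
        raise ValueError("group sizes must be non-negative")
    if sex_ratio <= 0:
        raise ValueError("sex_ratio must be positive")
    total = sum(n_per_group.values())
    if total == 0:
        raise ValueError("cohort must contain at least one sample")

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xC040]))
    rows = []
    idx = 0
    p_male = sex_ratio / (1.0 + sex_ratio)
    for diagnosis in DIAGNOSES:
        n = int(n_per_group.get(diagnosis, 0))
        if n == 0:
            continue
        if diagnosis in CANCER_CLASSES:
            params = _COV_PARAMS["cancer"]
        elif diagnosis == "HGD":
            params = _COV_PARAMS["hgd"]
        else:
            params = _COV_PARAMS["control"]
        covs = {}
        for cov in COVARIATE_COLUMNS:
            mean, sd = params[cov]
            lower = 18.0 if cov == "age" else 0.0
            covs[cov] = _truncated_normal(rng, mean, sd, lower, n)
        sex = np.where(rng.random(n) < p_male, "M", "F")
        epith = rng.beta(4.0, 6.0, size=n)
        for i in range(n):
            idx += 1
            rows.append({
                "sample_id": f"S{idx:04d}", "diagnosis": diagnosis,
                "age": covs["age"][i], "sex": sex[i], "bmi": covs["bmi"][i],
                "smoking": covs["smoking"][i], "alcohol": covs["alcohol"][i],
                "ppi": covs["ppi"][i], "heartburn": covs["heartburn"][i],
                "duplicate_of": None,
                "epithelial_fraction_true": float(epith[i]),
            })
    cohort = pd.DataFrame(rows)

    if n_duplicates > 0:
        sources = rng.choice(cohort.index.to_numpy(), size=n_duplicates,
                             replace=False)
        dup_rows = []
        for j, src in enumerate(sources, start=1):
            rec = cohort.loc[src].to_dict()
            rec["sample_id"] = f"D{j:04d}"
            rec["duplicate_of"] = cohort.loc[src, "sample_id"]
            dup_rows.append(rec)
        cohort = pd.concat([cohort, pd.DataFrame(dup_rows)], ignore_index=True)

    # provisional layout: 2 plates x 12 rows, filled round-robin
    n = len(cohort)
    order = rng.permutation(n)
    plate = np.empty(n, dtype=int)
    row = np.empty(n, dtype=int)
    plate[order] = (np.arange(n) // 12) % 2 + 1
    row[order] = np.arange(n) % 12 + 1
    cohort["plate"] = plate
    cohort["row"] = row
    return cohort


def _latent_gene_signals(cohort: pd.DataFrame, params: TruthParams,
                         rng: np.random.Generator):
    """Unit-variance latent gene x sample signals plus ground-truth records."""
    n_samples = len(cohort)
    originals = cohort["duplicate_of"].isna()
    n_orig = int(originals.sum())
    gene_ids = [f"GENE{i:04d}" for i in range(1, params.n_genes + 1)]

    if params.n_modules * params.module_size > params.n_genes:
        raise ValueError("module sizes exceed gene count")
    if params.module_size < 5:
        raise ValueError("every planted module needs >= 5 genes")

    assignment = {g: 0 for g in gene_ids}
    for m in range(1, params.n_modules + 1):
        for g in gene_ids[(m - 1) * params.module_size: m * params.module_size]:
            assignment[g] = m

    # module_cor targets the *observed* probe-level correlation; undo the
    # known attenuations: probe noise shrinks pairwise correlation by
    # s^2/(s^2+sigma^2) (s = logit_scale), and the logit->beta squashing by
    # a further ~0.87 (near-invariant over the baseline mixture used here).
    atten_probe = params.logit_scale ** 2 / (
        params.logit_scale ** 2 + params.probe_noise_sd ** 2)
    latent_cor = min(1.0, params.module_cor / (atten_probe * _SQUASH_ATTENUATION))
    loading = float(np.sqrt(latent_cor))
    factors = rng.standard_normal((params.n_modules, n_orig))
    noise = rng.standard_normal((params.n_genes, n_orig))
    z = np.empty((params.n_genes, n_orig))
    mod_vec = np.array([assignment[g] for g in gene_ids])
    for i, m in enumerate(mod_vec):
        if m == 0:
            z[i] = noise[i]
        else:
            z[i] = loading * factors[m - 1] + np.sqrt(max(0.0, 1 - loading**2)) * noise[i]

    is_cancer = cohort.loc[originals, "diagnosis"].isin(CANCER_CLASSES).to_numpy()
    disease_mask = np.isin(mod_vec, list(params.disease_modules))
    z[np.ix_(disease_mask, is_cancer)] += params.disease_effect

    # covariate-linked drift on random background genes
    cov_loadings: dict[str, dict[str, float]] = {}
    bg = np.flatnonzero(mod_vec == 0)
    rng.shuffle(bg)
    age_z = _standardize(cohort.loc[originals, "age"].to_numpy())
    smoke_z = _standardize(cohort.loc[originals, "smoking"].to_numpy())
    for gi in bg[: params.n_age_genes]:
        z[gi] += params.age_loading * age_z
        cov_loadings.setdefault(gene_ids[gi], {})["age"] = params.age_loading
    for gi in bg[params.n_age_genes: params.n_age_genes + params.n_smoking_genes]:
        z[gi] += params.smoking_loading * smoke_z
        cov_loadings.setdefault(gene_ids[gi], {})["smoking"] = params.smoking_loading

    # expand latent signals to every array (duplicates share their source's)
    src_index = {sid: k for k, sid in enumerate(cohort.loc[originals, "sample_id"])}
    col_of = np.array([
        src_index[sid if pd.isna(dup) else dup]
        for sid, dup in zip(cohort["sample_id"], cohort["duplicate_of"])
    ])
    return gene_ids, assignment, z[:, col_of], cov_loadings


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def generate_methylation(cohort: pd.DataFrame,
                         params: TruthParams | None = None,
                         seed: int = 0):
    """Generate a beta-value probe matrix for a cohort.

    Returns ``(ProbeMatrix, GroundTruth, annotation)`` where annotation maps
    probe_id -> gene_symbol (marker probes carry no gene and are dropped at
    the collapse stage, as unannotated loci are in the study pipeline).

    Construction: per-gene latent signals from a shared-factor module model
    (disease-module genes shifted in cancer samples), expanded to >= 1 probes
    per gene on the logit-beta scale with probe-level noise, additive
    (plate,row) batch shifts per probe block, cell-type mixing on a marker
    probe subset, and technical duplicates regenerated from the same latent
    sample with pair-specific noise.
    """
    if params is None:
        params = TruthParams()
    ss = np.random.SeedSequence([int(seed), 0x4D45])
    r_latent, r_probe, r_batch, r_marker, r_qc = (
        np.random.default_rng(s) for s in ss.spawn(5))

    gene_ids, assignment, z, cov_loadings = _latent_gene_signals(
        cohort, params, r_latent)
    n_samples = len(cohort)
    sample_ids = cohort["sample_id"].to_list()
    dup_mask = cohort["duplicate_of"].notna().to_numpy()

    # per-gene probe expansion on the logit scale
    n_probes_per_gene = r_probe.integers(1, params.max_probes_per_gene + 1,
                                         size=len(gene_ids))
    probe_rows, probe_ids, probe_gene = [], [], []
    duplicate_noise: dict[str, float] = {}
    dup_sds = np.resize(np.asarray(params.duplicate_noise_sds, dtype=float),
                        max(1, int(dup_mask.sum())))
    for k, sid in enumerate(np.asarray(sample_ids)[dup_mask]):
        duplicate_noise[str(sid)] = float(dup_sds[k])
    pair_sd = np.zeros(n_samples)
    pair_sd[dup_mask] = dup_sds[: int(dup_mask.sum())]

    # bimodal baseline typical of methylation arrays: the dominant mode is
    # unmethylated (M-value ~ -5, i.e. natural logit ~ -5*ln2), a smaller
    # methylated mode sits high, a minority of loci are intermediate
    _LN2 = float(np.log(2.0))
    pid = 0
    for gi, gene in enumerate(gene_ids):
        u = r_probe.random()
        if u < 0.55:
            base = r_probe.normal(-5.0 * _LN2, 0.6)
        elif u < 0.85:
            base = r_probe.normal(4.0 * _LN2, 0.6)
        else:
            base = r_probe.normal(0.0, 1.0)
        for _ in range(n_probes_per_gene[gi]):
            pid += 1
            offset = r_probe.normal(0.0, 0.3)
            noise = r_probe.normal(0.0, params.probe_noise_sd, size=n_samples)
            noise += r_probe.standard_normal(n_samples) * pair_sd
            probe_rows.append(base + offset + params.logit_scale * z[gi] + noise)
            probe_ids.append(f"cg{pid:08d}")
            probe_gene.append(gene)

    values = np.vstack(probe_rows)

    # additive (plate,row) batch shifts, constant per probe block
    batch_effects: dict[str, float] = {}
    plate = cohort["plate"].to_numpy()
    row = cohort["row"].to_numpy()
    units = sorted(set(zip(plate, row)))
    n_blocks = int(np.ceil(values.shape[0] / params.probe_block_size))
    for b in range(n_blocks):
        sl = slice(b * params.probe_block_size,
                   (b + 1) * params.probe_block_size)
        for (pl, rw) in units:
            shift = float(r_batch.normal(0.0, params.batch_sd)) if params.batch_sd > 0 else 0.0
            batch_effects[f"{b}|{pl}|{rw}"] = shift
            cols = (plate == pl) & (row == rw)
            values[sl][:, cols] += shift

    beta = _clamp_beta(expit(values))

    # marker probes: beta = f*epithelial + (1-f-fib)*immune + fib*fibroblast
    n_mark = params.n_marker_probes
    marker_ids = [f"mk{j:05d}" for j in range(1, n_mark + 1)]
    epi_ref = r_marker.beta(2.0, 2.0, size=n_mark)
    imm_ref = np.clip(epi_ref + r_marker.choice([-1, 1], size=n_mark) *
                      r_marker.uniform(0.3, 0.6, size=n_mark), 0.02, 0.98)
    fib_ref = r_marker.beta(2.0, 2.0, size=n_mark)
    f = cohort["epithelial_fraction_true"].to_numpy()
    fib = params.fibroblast_fraction
    mix = (np.outer(epi_ref, f) + np.outer(imm_ref, (1 - fib) - f)
           + np.outer(fib_ref, np.full(n_samples, fib)))
    mix += r_marker.normal(0.0, params.marker_noise_sd, size=mix.shape)
    marker_beta = _clamp_beta(mix)
    reference = pd.DataFrame(
        {"epithelial": epi_ref, "immune": imm_ref, "fibroblast": fib_ref},
        index=pd.Index(marker_ids, name="probe_id"))

    all_values = np.vstack([beta, marker_beta])
    all_ids = probe_ids + marker_ids
    frame = pd.DataFrame(all_values, index=pd.Index(all_ids, name="probe_id"),
                         columns=sample_ids)

    # simulated bisulfite-control intensities and planted QC failures
    intensity = r_qc.normal(params.control_intensity_mean,
                            params.control_intensity_sd, size=n_samples)
    intensity = np.clip(intensity, 100.0, None)
    eligible = np.flatnonzero(~dup_mask)
    r_qc.shuffle(eligible)
    for j in eligible[: params.n_bisulfite_failures]:
        intensity[j] = r_qc.uniform(300.0, 1800.0)
    fail_density = eligible[params.n_bisulfite_failures:
                            params.n_bisulfite_failures + params.n_density_failures]
    for j in fail_density:
        # systematic failure: density peak migrates to mid-range betas
        frame.iloc[:, j] = _clamp_beta(
            r_qc.normal(0.7, 0.08, size=frame.shape[0]))

    matrix = ProbeMatrix(frame, scale="beta",
                         control_intensity=pd.Series(intensity,
                                                     index=frame.columns))
    annotation = pd.DataFrame({"probe_id": probe_ids,
                               "gene_symbol": probe_gene})
    truth = GroundTruth(
        module_assignment_true=assignment,
        disease_modules=set(params.disease_modules),
        disease_effect=params.disease_effect,
        batch_effects=batch_effects,
        duplicate_noise=duplicate_noise,
        covariate_loadings=cov_loadings,
        marker_reference=reference,
    )
    return matrix, truth, annotation


def write_sample_sheet(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


def write_beta_matrix(matrix: ProbeMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t")


def write_annotation(annotation: pd.DataFrame, path) -> None:
    annotation.to_csv(path, index=False)
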