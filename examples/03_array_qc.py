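"""Array QC: KS-distance reproducibility, duplicate resolution, filters.

Each duplicate pair keeps the member whose beta distribution sits closer
(two-sample Kolmogorov-Smirnov distance) to the leave-one-out average
array; samples with bisulfite-control intensity < 2000 or an M-value
density peak away from -5 are removed outright.
"""

import methylpanel as mp
from methylpanel import qc

cohort = mp.generate_cohort(n_duplicates=8, seed=9)
params = mp.TruthParams(n_genes=400, n_modules=4, module_size=25,
                        n_bisulfite_failures=2, n_density_failures=2)
matrix, truth, _ = mp.generate_methylation(cohort, params, seed=9)
print("arrays before QC:", matrix.values.shape[1])

pairs = qc.duplicate_pairs_from_cohort(cohort, matrix.sample_ids)
deduped, dup_report = qc.resolve_duplicates(matrix, pairs)
print(f"duplicate pairs resolved: {len(pairs)} "
      f"(kept the lower-KS member of each)")
kept_ks = dup_report.loc[~dup_report["removed"], "ks_to_mean"]
lost_ks = dup_report.loc[dup_report["removed"], "ks_to_mean"]
print(f"  KS to average array - kept members: {kept_ks.mean():.3f} mean, "
      f"removed members: {lost_ks.mean():.3f} mean")

filtered, report = qc.qc_filter(deduped)
print("\nhard-filter removals:")
print(report["removal_reason"].value_counts().to_string())
print("arrays after QC:", filtered.values.shape[1])
print("(bisulfite = control intensity < 2000; density_outlier = M-value "
      "peak outside [-6.5, -3.5])")
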