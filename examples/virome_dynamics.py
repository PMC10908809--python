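"""Longitudinal virome summaries: diversity, retention, persistence.

Builds breadth-filtered RPKM abundances for a synthetic cohort, then
computes per-sample Shannon diversity, retention of month-1 vOTUs at later
infant timepoints, the persistent/transient virome partition, and the
per-sample abundance fraction of temperate phages.
"""

import warnings

import pandas as pd

from virotrace import (
    CohortConfig,
    apply_breadth_filter,
    bootstrap_ci,
    generate_cohort,
    persistence_partition,
    retention_metrics,
    rpkm_transform,
    shannon,
    temperate_fraction,
)

warnings.simplefilter("ignore")

bundle = generate_cohort(CohortConfig(n_families=6, n_votus=30, n_bacteria=5,
                                      seq_length=2000, seed=2))
filtered = apply_breadth_filter(bundle.coverage, threshold=0.75)
matrix = rpkm_transform(filtered, bundle.library_sizes)

meta = bundle.metadata.set_index("sample_id")
vlp = [c for c in matrix.columns
       if meta.loc[c, "source"] == "VLP" and matrix[c].sum() > 0]

div = pd.Series({c: shannon(matrix[c]) for c in vlp})
roles = meta.loc[vlp, "role"]
print("Shannon diversity (nats), mean by role:")
print(div.groupby(roles).mean().round(3).to_string())
print("  -> adult (maternal) viromes are richer and more even than infant ones")

# retention of the first infant timepoint in later samples of one infant
infant = meta[(meta["role"] == "infant") & (meta["source"] == "VLP")]
one = infant[infant["individual_id"] == infant["individual_id"].iloc[0]]
tps = one.sort_values("age_days")
base = matrix[tps.index[0]]
pcts = []
for later_sid in tps.index[1:]:
    r = retention_metrics(base, matrix[later_sid],
                          baseline_label=tps["timepoint_label"].iloc[0],
                          later_label=meta.loc[later_sid, "timepoint_label"])
    pcts.append(r.pct_of_richness)
    print(f"retention {r.baseline_label}->{r.later_label}: "
          f"{r.n_retained} vOTUs kept, {r.pct_of_richness:.1f}% of later "
          f"richness, {r.cum_rel_abund:.1f}% of later abundance")
if len(pcts) > 1:
    lo, hi = bootstrap_ci(pcts, seed=0)
    print(f"  mean retained richness {sum(pcts)/len(pcts):.1f}% "
          f"(bootstrap 95% CI [{lo:.1f}, {hi:.1f}])")

# persistent vs transient virome of that infant
part = persistence_partition(matrix[list(tps.index)], threshold=0.75)
print(f"persistent virome: {len(part.ppv_ids)} vOTUs present in >=75% of "
      f"samples; transient: {len(part.tdv_ids)}")

frac = temperate_fraction(matrix[vlp], bundle.lifestyle)
print("temperate-phage abundance fraction, mean by role:")
print(frac.groupby(roles).mean().round(3).to_string())
print("  -> infant viromes carry a larger share of temperate (prophage-"
      "derived) phages")
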