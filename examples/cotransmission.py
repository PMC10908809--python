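"""Phage-host co-transmission: partial Mantel and non-random linkage.

Runs the pipeline on a cohort where every transmitted phage is coupled to
its predicted bacterial host (the host strain travels with the phage), then
shows the per-pair linkage statistics and the host-vs-random enrichment.
"""

import warnings

from virotrace import CohortConfig, RunConfig, host_vs_random_enrichment, run_pipeline

warnings.simplefilter("ignore")

cohort = CohortConfig(
    n_families=6, n_votus=10, n_bacteria=10,
    transmission_rate=0.4, coupling_rate=1.0,
    seq_length=6000, seed=5,
)
out = run_pipeline(RunConfig(synthetic=cohort, seed=5))

linkage = out["linkage"]
cols = ["pair_id", "pair_class", "mantel_r", "p_mantel", "q_mantel",
        "nonrandom_linkage", "status", "cotransmitted"]
print(linkage[cols].round(4).to_string(index=False))
print()
print("mantel_r correlates the binarised sharing matrices of phage and")
print("bacterium over concurrent samples, controlling for repeated sampling")
print("of the same individual; nonrandom_linkage is the excess joint-sharing")
print("frequency over independence (positive = co-transmission).")

ok = linkage[linkage["status"] == "ok"]
host = ok.loc[ok["pair_class"] == "host", "cotransmitted"]
rand = ok.loc[ok["pair_class"] == "random", "cotransmitted"]
p = host_vs_random_enrichment(host.tolist(), rand.tolist())
print(f"\nhost pairs co-transmitted: {int(host.sum())}/{len(host)}, "
      f"random pairs: {int(rand.sum())}/{len(rand)}; "
      f"one-sided Fisher p = {p:.4g}")
print("note: pairs whose sharing pattern repeats the same-individual")
print("structure are collinear with the control matrix and skipped; and a")
print("random partner that was itself transmitted shares the family-block")
print("structure, so it can correlate without mechanistic coupling — the")
print("reason this host-vs-random comparison exists.")
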