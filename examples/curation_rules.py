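"""Viral scaffold curation on a small annotation table.

Shows the six inclusion criteria, genus-cluster (VC) decontamination with
member rescue, and temperate/virulent lifestyle calling on a handful of
scaffolds with contrasting feature profiles.
"""

import pandas as pd

from virotrace import curate

defaults = dict(
    length_bp=2000, circular=False, virsorter_positive=False, pvog_hits=0,
    pvog_per_10kb=0.0, ribosomal_protein_genes=0, rrna_hit=False,
    refseq_viral_hit=False, crass_hit=False, nt_hit=False,
    negctrl_cluster=False, checkv_quality="Low-quality",
    integrase=False, recombinase=False, ci_repressor=False,
)

rows = [
    dict(defaults, scaffold_id="circ_phage", vc_id="VC1", circular=True,
         integrase=True),
    dict(defaults, scaffold_id="refseq_hit", vc_id="VC1",
         refseq_viral_hit=True),
    dict(defaults, scaffold_id="rrna_contam", vc_id="VC2", rrna_hit=True,
         virsorter_positive=False, refseq_viral_hit=True),
    dict(defaults, scaffold_id="rescued_member", vc_id="VC2", circular=True,
         pvog_hits=2, pvog_per_10kb=10.0),
    dict(defaults, scaffold_id="dark_matter", vc_id="VC3", length_bp=4500),
    dict(defaults, scaffold_id="featureless", vc_id="VC4"),
]
annotations = pd.DataFrame(rows)

curated = curate(annotations)
print(curated[["scaffold_id", "criteria_hit", "lifestyle"]].to_string(index=False))
print()
print("criteria_hit: which of the six viral-evidence rules fired (4 =")
print("circular, 1 = RefSeq-viral hit, 6 = >3 kbp with no nt-database hit).")
print("'rrna_contam' condemned its whole cluster VC2, but 'rescued_member'")
print("survived because it is circular with pVOG hits; 'featureless' never")
print("looked viral in the first place.")
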