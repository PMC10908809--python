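"""Hand-enumerated 20-scaffold annotation fixture (synthetic).

Every expected outcome below was derived by hand from the curation rules:
inclusion criteria 1-6, negative-control exclusion, VC condemnation rules
(a) rRNA, (b) ribosomal proteins with sparse pVOGs and no VirSorter/circular
support, (c) >3 ribosomal proteins, member rescues (r1) circular+pVOG,
(r2) circular+VirSorter, (r3) VirSorter+no ribosomal proteins, and the
temperate rule (integrase, or recombinase+CI repressor).
"""

import pandas as pd

_DEFAULTS = dict(
    length_bp=2000, circular=False, virsorter_positive=False, pvog_hits=0,
    pvog_per_10kb=0.0, ribosomal_protein_genes=0, rrna_hit=False,
    refseq_viral_hit=False, crass_hit=False, nt_hit=False,
    negctrl_cluster=False, checkv_quality="Low-quality",
    integrase=False, recombinase=False, ci_repressor=False,
)


def _row(sid, vc, **kw):
    row = dict(_DEFAULTS, scaffold_id=sid, vc_id=vc)
    row.update(kw)
    return row


def build_fixture() -> pd.DataFrame:
    rows = [
        # inclusion criteria, one each (singleton VCs, nothing condemning)
        _row("S01", "VC_S01", refseq_viral_hit=True),
        _row("S02", "VC_S02", pvog_hits=3, pvog_per_10kb=15.0, integrase=True),
        _row("S03", "VC_S03", virsorter_positive=True,
             recombinase=True, ci_repressor=True),
        _row("S04", "VC_S04", circular=True, recombinase=True),
        _row("S05", "VC_S05", crass_hit=True),
        _row("S06", "VC_S06", length_bp=3500),
        # negatives for the inclusion stage
        _row("S07", "VC_S07", length_bp=3500, nt_hit=True),
        _row("S08", "VC_S08"),
        _row("S09", "VC_S09", pvog_hits=2, pvog_per_10kb=10.0),
        _row("S10", "VC_S10", length_bp=12000, pvog_hits=3,
             pvog_per_10kb=2.5, nt_hit=True),
        _row("S11", "VC_S11", length_bp=20000, pvog_hits=3,
             pvog_per_10kb=1.5, nt_hit=True),
        # negative-control cluster exclusion
        _row("S12", "VC_S12", circular=True, negctrl_cluster=True),
        # VC_B: condemned by S13 (rRNA); S14/S15 rescued, S13/S16 not
        _row("S13", "VC_B", rrna_hit=True, ribosomal_protein_genes=1,
             refseq_viral_hit=True),
        _row("S14", "VC_B", circular=True, pvog_hits=2, pvog_per_10kb=10.0,
             integrase=True),
        _row("S15", "VC_B", virsorter_positive=True),
        _row("S16", "VC_B", refseq_viral_hit=True),
        # VC_C: no condemning member, passes whole
        _row("S17", "VC_C", virsorter_positive=True, ribosomal_protein_genes=1,
             pvog_hits=1, pvog_per_10kb=5.0),
        _row("S18", "VC_C", circular=True),
        # VC_D: condemned by S19 (>3 ribosomal proteins); S20 rescued (r2)
        _row("S19", "VC_D", ribosomal_protein_genes=4, refseq_viral_hit=True),
        _row("S20", "VC_D", circular=True, virsorter_positive=True),
    ]
    from virotrace.io import ANNOTATION_COLUMNS

    return pd.DataFrame(rows)[ANNOTATION_COLUMNS]


#: scaffold -> criteria that fire (hand enumeration); absent = not viral
EXPECTED_CRITERIA = {
    "S01": "1", "S02": "2", "S03": "3", "S04": "4", "S05": "5", "S06": "6",
    "S10": "2", "S12": "4", "S13": "1", "S14": "4", "S15": "3", "S16": "1",
    "S17": "3", "S18": "4", "S19": "1", "S20": "3,4",
}

#: scaffolds surviving all three stages (hand enumeration)
EXPECTED_RETAINED = [
    "S01", "S02", "S03", "S04", "S05", "S06", "S10",
    "S14", "S15", "S17", "S18", "S20",
]

#: lifestyle of retained scaffolds (hand enumeration of the temperate rule)
EXPECTED_LIFESTYLE = {
    "S01": "virulent", "S02": "temperate", "S03": "temperate",
    "S04": "virulent", "S05": "virulent", "S06": "virulent",
    "S10": "virulent", "S14": "temperate", "S15": "virulent",
    "S17": "virulent", "S18": "virulent", "S20": "virulent",
}
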