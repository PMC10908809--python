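"""Viral scaffold curation: inclusion criteria, decontamination, lifestyle.

Operates on precomputed per-scaffold annotation features (BLAST/HMM/
VirSorter/CheckV outputs arrive as a feature table; running those tools is
out of scope).  Four stages:

1. *Inclusion* — a scaffold >=1 kbp is putatively viral if it satisfies at
   least one of six criteria (RefSeq-viral hit; >=3 pVOG ORF hits at >=2 per
   10 kb; VirSorter-positive; circular; Crassvirales hit; >3 kbp with no nt
   hit).
2. *Negative-control dereplication* — 99%-ANI clusters that contain a
   negative-control scaffold are discarded wholesale.
3. *Genus-cluster (VC) decontamination* — a VC is condemned when any member
   looks cellular (rRNA gene; ribosomal proteins with sparse pVOG signal and
   no VirSorter/circularity support; >3 ribosomal proteins), but individual
   members with strong viral evidence are rescued.
4. *Lifestyle* — temperate iff an integrase gene is present, or a
   recombinase gene co-occurs with a CI-repressor-like gene.

Strain-level candidate selection keeps vOTUs with (near-)complete genomes,
length >= 3 kbp, and presence (breadth > 0.95) in both the mother and an
infant of at least five distinct families.
"""

from __future__ import annotations

import warnings

import pandas as pd

__all__ = [
    "classify_viral",
    "exclude_negative_control_clusters",
    "vc_decontaminate",
    "call_lifestyle",
    "select_strain_candidates",
    "curate",
]


def classify_viral(annotations: pd.DataFrame) -> pd.DataFrame:
    """Apply the six viral inclusion criteria.

    Returns a copy with boolean ``is_viral`` and a ``criteria_hit`` column
    holding the sorted criterion numbers that fired (comma-separated, e.g.
    ``"2,4"``).  Scaffolds shorter than 1 kbp violate the pre-filter and
    raise.
    """
    ann = annotations.copy()
    if (ann["length_bp"] < 1000).any():
        bad = ann.loc[ann["length_bp"] < 1000, "scaffold_id"].tolist()
        raise ValueError(f"scaffolds below the 1 kbp pre-filter: {bad[:5]}")
    crit = pd.DataFrame(index=ann.index)
    crit[1] = ann["refseq_viral_hit"]
    crit[2] = (ann["pvog_hits"] >= 3) & (ann["pvog_per_10kb"] >= 2.0)
    crit[3] = ann["virsorter_positive"]
    crit[4] = ann["circular"]
    crit[5] = ann["crass_hit"]
    crit[6] = (ann["length_bp"] > 3000) & ~ann["nt_hit"]
    ann["criteria_hit"] = crit.apply(
        lambda row: ",".join(str(c) for c in crit.columns[row.values]), axis=1
    )
    ann["is_viral"] = crit.any(axis=1)
    return ann


def exclude_negative_control_clusters(annotations: pd.DataFrame) -> pd.DataFrame:
    """Drop every scaffold whose 99%-ANI cluster contains a negative control."""
    flagged = annotations["negctrl_cluster"]
    if flagged.all() and len(annotations):
        warnings.warn(
            "all scaffolds fall in negative-control clusters; nothing retained",
            stacklevel=2,
        )
    return annotations[~flagged].copy()


def _condemning(member: pd.Series) -> bool:
    if member["rrna_hit"]:
        return True
    if (
        member["ribosomal_protein_genes"] >= 1
        and member["pvog_per_10kb"] < 3.0
        and not member["virsorter_positive"]
        and not member["circular"]
    ):
        return True
    return member["ribosomal_protein_genes"] > 3


def _rescued(member: pd.Series) -> bool:
    if member["circular"] and member["pvog_hits"] >= 1:
        return True
    if member["circular"] and member["virsorter_positive"]:
        return True
    return member["virsorter_positive"] and member["ribosomal_protein_genes"] == 0


def vc_decontaminate(annotations: pd.DataFrame) -> pd.DataFrame:
    """Second-stage decontamination at the genus-cluster (VC) level.

    A VC is condemned when *any* member triggers a condemnation rule; members
    of condemned VCs survive only through an individual rescue rule (rescue
    takes precedence for that member).  VCs with no condemning member pass
    whole.  Singletons/outliers are their own VC (distinct ``vc_id``).
    """
    condemned_vcs = {
        vc for vc, group in annotations.groupby("vc_id")
        if group.apply(_condemning, axis=1).any()
    }
    keep = annotations.apply(
        lambda m: m["vc_id"] not in condemned_vcs or _rescued(m), axis=1
    )
    return annotations[keep].copy()


def call_lifestyle(annotations: pd.DataFrame) -> pd.Series:
    """Temperate/virulent call from phage gene content.

    Temperate iff integrase present, or recombinase AND CI-repressor-like
    genes co-present; depends only on these three flags.
    """
    temperate = annotations["integrase"] | (
        annotations["recombinase"] & annotations["ci_repressor"]
    )
    out = pd.Series(
        pd.array(["temperate" if t else "virulent" for t in temperate]),
        index=annotations["scaffold_id"].values,
        name="lifestyle",
        dtype=str,
    )
    return out


def select_strain_candidates(
    breadth: pd.DataFrame,
    annotations: pd.DataFrame,
    metadata: pd.DataFrame,
    min_breadth: float = 0.95,
    min_length: int = 3000,
    min_families: int = 5,
) -> list[str]:
    """vOTUs eligible for strain (consensus-sequence) reconstruction.

    Keep vOTUs with (1) a CheckV high-quality/complete genome or a
    circularised genome, (2) length >= ``min_length``, and (3) presence —
    breadth strictly above ``min_breadth`` — in both a maternal and an infant
    sample of the same family, for at least ``min_families`` distinct
    families.

    ``breadth`` is a scaffold x sample matrix of coverage breadths.
    """
    ann = annotations.set_index("scaffold_id")
    quality_ok = (
        ann["checkv_quality"].isin(["High-quality", "Complete"]) | ann["circular"]
    )
    length_ok = ann["length_bp"] >= min_length
    meta = metadata.set_index("sample_id")
    candidates = []
    for votu in breadth.index:
        if votu not in ann.index or not (quality_ok[votu] and length_ok[votu]):
            continue
        present = breadth.columns[breadth.loc[votu] > min_breadth]
        roles = meta.loc[meta.index.intersection(present), ["family_id", "role"]]
        fam_roles = roles.groupby("family_id")["role"].agg(set)
        shared = fam_roles[fam_roles.apply(lambda s: {"mother", "infant"} <= s)]
        if len(shared) >= min_families:
            candidates.append(votu)
    return candidates


def curate(annotations: pd.DataFrame) -> pd.DataFrame:
    """Full curation: inclusion -> negative-control -> VC decontamination,
    with lifestyle labels attached to the retained scaffolds."""
    ann = classify_viral(annotations)
    ann = ann[ann["is_viral"]]
    ann = exclude_negative_control_clusters(ann)
    ann = vc_decontaminate(ann)
    ann = ann.copy()
    ann["lifestyle"] = call_lifestyle(ann).values
    return ann.reset_index(drop=True)
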