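"""Readers and writers for the tabular and sequence formats of the pipeline.

All tables are UTF-8 TSV with mandatory headers; strain alignments are FASTA
(one file per entity, sample_id as record id, 80-column wrap).  Every reader
validates its header and id uniqueness and raises with file context; write
followed by read restores an equal object.
"""

from __future__ import annotations

import os
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .distances import StrainAlignment

__all__ = [
    "read_metadata", "write_metadata",
    "read_coverage", "write_coverage",
    "read_abundance", "write_abundance",
    "read_alignment_fasta", "write_alignment_fasta",
    "read_host_map", "write_host_map",
    "read_annotations", "write_annotations",
    "read_truth", "write_truth",
]

METADATA_COLUMNS = [
    "sample_id", "individual_id", "family_id", "role", "timepoint_label",
    "age_days", "source", "library_size", "dna_conc",
]
COVERAGE_COLUMNS = [
    "scaffold_id", "sample_id", "read_count", "breadth", "scaffold_length",
]
HOST_MAP_COLUMNS = ["virus_id", "host_id", "confidence"]
TRUTH_COLUMNS = ["entity_id", "kind", "transmitted", "coupled_host_id"]
ANNOTATION_COLUMNS = [
    "scaffold_id", "length_bp", "circular", "virsorter_positive", "pvog_hits",
    "pvog_per_10kb", "ribosomal_protein_genes", "rrna_hit", "refseq_viral_hit",
    "crass_hit", "nt_hit", "vc_id", "negctrl_cluster", "checkv_quality",
    "integrase", "recombinase", "ci_repressor",
]

_BOOL_MAP = {"true": True, "false": False, "1": True, "0": False}


def _check_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def _check_unique(df: pd.DataFrame, col: str, path) -> None:
    dup = df[col][df[col].duplicated()]
    if not dup.empty:
        raise ValueError(
            f"{path}: duplicate {col} value(s): {sorted(dup.unique())[:5]}"
        )


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def _to_bool(s: pd.Series, path) -> pd.Series:
    vals = s.str.lower().map(_BOOL_MAP)
    if vals.isna().any():
        bad = s[vals.isna()].iloc[0]
        raise ValueError(f"{path}: non-boolean value {bad!r} in column {s.name!r}")
    return vals.astype(bool)


def read_metadata(path) -> pd.DataFrame:
    df = _read_tsv(path)
    _check_columns(df, METADATA_COLUMNS, path)
    _check_unique(df, "sample_id", path)
    bad_role = set(df["role"]) - {"mother", "infant"}
    if bad_role:
        raise ValueError(f"{path}: invalid role value(s) {sorted(bad_role)}")
    bad_src = set(df["source"]) - {"VLP", "MGS", "TOTAL"}
    if bad_src:
        raise ValueError(f"{path}: invalid source value(s) {sorted(bad_src)}")
    df["age_days"] = df["age_days"].astype(float)
    df["library_size"] = df["library_size"].astype(int)
    if (df["library_size"] <= 0).any():
        raise ValueError(f"{path}: library_size must be > 0")
    df["dna_conc"] = df["dna_conc"].astype(float)
    return df[METADATA_COLUMNS]


def write_metadata(df: pd.DataFrame, path) -> None:
    df[METADATA_COLUMNS].to_csv(path, sep="\t", index=False)


def read_coverage(path) -> pd.DataFrame:
    df = _read_tsv(path)
    _check_columns(df, COVERAGE_COLUMNS, path)
    df["read_count"] = df["read_count"].astype(int)
    df["breadth"] = df["breadth"].astype(float)
    df["scaffold_length"] = df["scaffold_length"].astype(int)
    if ((df["breadth"] < 0) | (df["breadth"] > 1)).any():
        raise ValueError(f"{path}: breadth must lie in [0, 1]")
    if (df["read_count"] < 0).any():
        raise ValueError(f"{path}: read_count must be >= 0")
    if (df["scaffold_length"] <= 0).any():
        raise ValueError(f"{path}: scaffold_length must be > 0")
    _check_unique(df.assign(key=df["scaffold_id"] + "\x00" + df["sample_id"]),
                  "key", path)
    return df[COVERAGE_COLUMNS]


def write_coverage(df: pd.DataFrame, path) -> None:
    df[COVERAGE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_abundance(path) -> pd.DataFrame:
    """Entity x sample abundance matrix; first column is ``entity_id``."""
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "entity_id":
        raise ValueError(f"{path}: first column must be 'entity_id'")
    df = df.set_index("entity_id")
    if df.index.duplicated().any():
        raise ValueError(f"{path}: duplicate entity_id rows")
    if (df.values < 0).any():
        raise ValueError(f"{path}: abundance values must be non-negative")
    return df


def write_abundance(matrix: pd.DataFrame, path) -> None:
    matrix.rename_axis("entity_id").to_csv(path, sep="\t")


def read_alignment_fasta(path, entity_id: str | None = None) -> StrainAlignment:
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"{path}: duplicate record id {rec.id!r}")
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    if entity_id is None:
        entity_id = Path(path).stem
    try:
        return StrainAlignment(entity_id, records)
    except ValueError as err:
        raise ValueError(f"{path}: {err}") from None


def write_alignment_fasta(aln: StrainAlignment, path) -> None:
    recs = [
        SeqRecord(Seq(seq), id=sid, description="")
        for sid, seq in aln.records.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=80)
        writer.write_file(recs)


def read_host_map(path) -> pd.DataFrame:
    """Virus -> predicted host; ties resolved to the highest confidence."""
    df = _read_tsv(path)
    _check_columns(df, HOST_MAP_COLUMNS, path)
    df["confidence"] = df["confidence"].astype(float)
    df = (
        df.sort_values(["virus_id", "confidence"], ascending=[True, False])
        .drop_duplicates("virus_id", keep="first")
        .reset_index(drop=True)
    )
    return df[HOST_MAP_COLUMNS]


def write_host_map(df: pd.DataFrame, path) -> None:
    df[HOST_MAP_COLUMNS].to_csv(path, sep="\t", index=False)


def read_annotations(path) -> pd.DataFrame:
    df = _read_tsv(path)
    _check_columns(df, ANNOTATION_COLUMNS, path)
    _check_unique(df, "scaffold_id", path)
    for col in ("circular", "virsorter_positive", "rrna_hit", "refseq_viral_hit",
                "crass_hit", "nt_hit", "negctrl_cluster", "integrase",
                "recombinase", "ci_repressor"):
        df[col] = _to_bool(df[col], path)
    for col in ("length_bp", "pvog_hits", "ribosomal_protein_genes"):
        df[col] = df[col].astype(int)
    df["pvog_per_10kb"] = df["pvog_per_10kb"].astype(float)
    return df[ANNOTATION_COLUMNS]


def write_annotations(df: pd.DataFrame, path) -> None:
    df[ANNOTATION_COLUMNS].to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    df = _read_tsv(path)
    _check_columns(df, TRUTH_COLUMNS, path)
    _check_unique(df, "entity_id", path)
    df["transmitted"] = _to_bool(df["transmitted"], path)
    return df[TRUTH_COLUMNS]


def write_truth(df: pd.DataFrame, path) -> None:
    df[TRUTH_COLUMNS].to_csv(path, sep="\t", index=False)


def write_bundle(bundle, outdir) -> None:
    """Write a synthetic cohort bundle in the formats the pipeline reads."""
    outdir = Path(outdir)
    os.makedirs(outdir / "alignments", exist_ok=True)
    write_metadata(bundle.metadata, outdir / "metadata.tsv")
    write_coverage(bundle.coverage, outdir / "coverage.tsv")
    write_annotations(bundle.annotations, outdir / "annotations.tsv")
    write_host_map(bundle.host_map, outdir / "host_map.tsv")
    write_truth(bundle.truth, outdir / "truth.tsv")
    for entity, aln in bundle.alignments.items():
        write_alignment_fasta(aln, outdir / "alignments" / f"{entity}.fasta")


def read_bundle_inputs(indir) -> dict:
    """Read pipeline inputs written by :func:`write_bundle`."""
    indir = Path(indir)
    alignments = {}
    aln_dir = indir / "alignments"
    if aln_dir.is_dir():
        for f in sorted(aln_dir.glob("*.fasta")):
            alignments[f.stem] = read_alignment_fasta(f)
    out = {
        "metadata": read_metadata(indir / "metadata.tsv"),
        "coverage": read_coverage(indir / "coverage.tsv"),
        "annotations": read_annotations(indir / "annotations.tsv"),
        "host_map": read_host_map(indir / "host_map.tsv"),
        "alignments": alignments,
    }
    truth_path = indir / "truth.tsv"
    if truth_path.exists():
        out["truth"] = read_truth(truth_path)
    return out
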