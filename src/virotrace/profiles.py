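"""Count-level filters and transforms that define the abundance matrices.

Mapped read counts per (scaffold, sample) pass a coverage-breadth gate —
spurious alignments rarely cover a scaffold evenly, so counts with breadth
below 75% of scaffold length are zeroed — and are then scaled to RPKM
(reads per kilobase of scaffold per million mapped reads).  vOTU abundances
can be aggregated by the predicted bacterial host taxon.
"""

from __future__ import annotations

import warnings

import pandas as pd

__all__ = [
    "apply_breadth_filter",
    "rpkm_transform",
    "coverage_to_matrix",
    "aggregate_by_host",
    "UNASSIGNED",
]

UNASSIGNED = "unassigned"


def apply_breadth_filter(records: pd.DataFrame, threshold: float = 0.75
                         ) -> pd.DataFrame:
    """Zero read counts where coverage breadth is below ``threshold``.

    The comparison is strict: a record with breadth exactly at the threshold
    is retained.  Idempotent; returns a copy.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must lie in (0, 1], got {threshold}")
    out = records.copy()
    out.loc[out["breadth"] < threshold, "read_count"] = 0
    return out


def rpkm_transform(records: pd.DataFrame, library_sizes: pd.Series
                   ) -> pd.DataFrame:
    """Turn (breadth-filtered) coverage records into an RPKM matrix.

    RPKM = read_count / (scaffold_length/1e3) / (library_size/1e6).  The
    library size is the per-sample total of mapped reads (configurable
    upstream; any consistent per-sample total keeps columns comparable).
    Returns a scaffold x sample matrix with absent pairs as 0.
    """
    missing = sorted(set(records["sample_id"]) - set(library_sizes.index))
    if missing:
        raise ValueError(f"missing library size for sample(s): {missing}")
    if (library_sizes <= 0).any():
        bad = library_sizes[library_sizes <= 0].index.tolist()
        raise ValueError(f"library_size must be > 0 (samples {bad})")
    if (records["scaffold_length"] <= 0).any():
        raise ValueError("scaffold_length must be > 0")
    rec = records.copy()
    lib = library_sizes.loc[rec["sample_id"]].to_numpy(dtype=float)
    rec["rpkm"] = (
        rec["read_count"].to_numpy(dtype=float)
        / (rec["scaffold_length"].to_numpy(dtype=float) / 1e3)
        / (lib / 1e6)
    )
    return coverage_to_matrix(rec, value="rpkm")


def coverage_to_matrix(records: pd.DataFrame, value: str = "read_count"
                       ) -> pd.DataFrame:
    matrix = records.pivot_table(
        index="scaffold_id", columns="sample_id", values=value,
        aggfunc="sum", fill_value=0.0,
    )
    matrix.index.name = "entity_id"
    matrix.columns.name = None
    return matrix.astype(float)


def aggregate_by_host(matrix: pd.DataFrame, host_map: pd.DataFrame | dict
                      ) -> pd.DataFrame:
    """Sum vOTU abundances per predicted host taxon.

    ``host_map`` maps virus_id -> host taxon (a dict, or a table with
    ``virus_id``/``host_id`` columns already de-duplicated to the
    highest-confidence host).  vOTUs without a host land in ``unassigned``;
    mapped vOTUs absent from the matrix are skipped with a warning.
    Aggregation conserves the per-sample total.
    """
    if isinstance(host_map, pd.DataFrame):
        mapping = dict(zip(host_map["virus_id"], host_map["host_id"]))
    else:
        mapping = dict(host_map)
    unknown = sorted(set(mapping) - set(matrix.index))
    if unknown:
        warnings.warn(
            f"{len(unknown)} mapped vOTU(s) absent from the matrix, skipped: "
            f"{unknown[:5]}",
            stacklevel=2,
        )
    groups = pd.Series(
        [mapping.get(v, UNASSIGNED) or UNASSIGNED for v in matrix.index],
        index=matrix.index,
    )
    out = matrix.groupby(groups).sum()
    out.index.name = "entity_id"
    return out
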