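"""Kimura 2-parameter strain distances from consensus-sequence alignments.

Strain-level comparisons between samples are made on per-entity (vOTU or
bacterial species) multiple sequence alignments of consensus sequences, one
record per sample.  Alignments are end-trimmed (gap-enriched flanks), pairwise
distances are computed under the Kimura two-parameter (K80) model,

    d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))

with P the proportion of transition differences (A<->G, C<->T) and Q the
proportion of transversion differences among compared sites, and the matrix is
normalised by a per-entity median so that cutoffs are comparable across
entities with different mutation-rate scales.

Ambiguous positions (gaps, N) are removed per *pair* of sequences by default:
a column is skipped for a pair only if either member is ambiguous there, which
wastes less signal than deleting the column for every pair.  Global
("complete") deletion is available for strict replication of distance tools
that drop a column when any record is ambiguous.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StrainAlignment",
    "StrainDistanceSet",
    "trim_alignment",
    "k2p_distance",
    "pairwise_k2p",
    "median_normalize",
    "SaturationWarning",
]

# A=0 C=1 G=2 T=3; XOR of two codes equals 2 exactly for transitions.
_CODE = np.full(256, 255, dtype=np.uint8)
for _b, _i in zip(b"ACGT", range(4)):
    _CODE[_b] = _i
    _CODE[ord(chr(_b).lower())] = _i


class SaturationWarning(UserWarning):
    """A pair of sequences is too diverged for the K80 estimator."""


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass
class StrainAlignment:
    """Per-entity alignment: sample_id -> aligned sequence over {A,C,G,T,N,-}."""

    entity_id: str
    records: dict[str, str]

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise ValueError(
                f"alignment for {self.entity_id!r} needs >=2 records, "
                f"got {len(self.records)}"
            )
        lengths = {len(s) for s in self.records.values()}
        if len(lengths) != 1:
            raise ValueError(
                f"ragged alignment for {self.entity_id!r}: lengths {sorted(lengths)}"
            )

    @property
    def length(self) -> int:
        return len(next(iter(self.records.values())))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.records)

    def matrix(self) -> np.ndarray:
        """(n_records, length) uint8 codes; 255 marks gap/ambiguous."""
        return np.vstack([_encode(s) for s in self.records.values()])


@dataclass
class StrainDistanceSet:
    """Symmetric K2P distance matrix over the samples carrying one strain.

    ``D`` is in substitutions/site (NaN where the estimator saturated),
    ``D_norm`` is ``D`` divided by ``normalizer`` (the entity's median
    distance; see :func:`median_normalize`), and ``valid_sites`` counts the
    alignment columns compared for each pair.
    """

    entity_id: str
    sample_ids: list[str]
    D: np.ndarray
    valid_sites: np.ndarray
    D_norm: np.ndarray | None = None
    normalizer: float | None = None
    P: np.ndarray = field(default=None, repr=False)
    Q: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        if self.D.shape != (n, n):
            raise ValueError("distance matrix shape does not match sample_ids")

    def index_of(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)


def trim_alignment(aln: StrainAlignment, trim_bp: int = 100) -> StrainAlignment:
    """Remove ``trim_bp`` columns from both ends of the alignment.

    Global alignments of consensus sequences accumulate gaps at their flanks;
    trimming 100 bp from each end (the default) removes them before distance
    estimation.
    """
    if trim_bp < 0:
        raise ValueError("trim_bp must be >= 0")
    if trim_bp == 0:
        return aln
    if aln.length <= 2 * trim_bp:
        raise ValueError(
            f"alignment for {aln.entity_id!r} has {aln.length} columns, "
            f"too short to trim {trim_bp} bp from both ends"
        )
    records = {sid: seq[trim_bp:-trim_bp] for sid, seq in aln.records.items()}
    return StrainAlignment(aln.entity_id, records)


def k2p_distance(s1: str, s2: str) -> tuple[float, float, float, int]:
    """K2P distance between two aligned sequences.

    Returns ``(d, P, Q, n_sites)`` where sites are the columns at which both
    sequences carry an unambiguous base.  ``d`` is NaN (with a
    :class:`SaturationWarning`) when the observed P, Q fall outside the model's
    valid region, i.e. ``1 - 2P - Q <= 0`` or ``1 - 2Q <= 0``.
    """
    if len(s1) != len(s2):
        raise ValueError("sequences must be aligned to equal length")
    a, b = _encode(s1), _encode(s2)
    valid = (a < 4) & (b < 4)
    n = int(valid.sum())
    if n == 0:
        raise ValueError("no comparable (unambiguous) sites between sequences")
    diff = (a != b) & valid
    ts = int((((a ^ b) == 2) & valid).sum())
    tv = int(diff.sum()) - ts
    P, Q = ts / n, tv / n
    d = _k2p_from_pq(P, Q)
    if np.isnan(d):
        warnings.warn(
            f"saturated pair (P={P:.3f}, Q={Q:.3f}); distance set to NaN",
            SaturationWarning,
            stacklevel=2,
        )
    return d, P, Q, n


def _k2p_from_pq(P, Q):
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(
            (w1 > 0) & (w2 > 0),
            -0.5 * np.log(np.where(w1 > 0, w1, 1.0))
            - 0.25 * np.log(np.where(w2 > 0, w2, 1.0)),
            np.nan,
        )
    return d if d.ndim else float(d)


def pairwise_k2p(
    aln: StrainAlignment, *, deletion: str = "pairwise"
) -> StrainDistanceSet:
    """All-pairs K2P distances for a (trimmed) strain alignment.

    ``deletion='pairwise'`` skips a column only for the pairs in which either
    member is a gap/N; ``deletion='complete'`` drops columns ambiguous in any
    record before comparing (the convention of classic distance tools).
    Saturated pairs become NaN with a warning; pairs with zero comparable
    sites likewise.
    """
    if deletion not in ("pairwise", "complete"):
        raise ValueError("deletion must be 'pairwise' or 'complete'")
    X = aln.matrix()
    valid = X < 4
    if deletion == "complete":
        keep = valid.all(axis=0)
        X, valid = X[:, keep], valid[:, keep]
    n = X.shape[0]
    D = np.zeros((n, n))
    Pm = np.zeros((n, n))
    Qm = np.zeros((n, n))
    sites = np.zeros((n, n), dtype=np.int64)
    np.fill_diagonal(sites, valid.sum(axis=1))
    for i in range(n - 1):
        rest = slice(i + 1, n)
        both = valid[i] & valid[rest]
        ns = both.sum(axis=1)
        ts = (((X[i] ^ X[rest]) == 2) & both).sum(axis=1)
        df = ((X[i] != X[rest]) & both).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            P = np.where(ns > 0, ts / np.maximum(ns, 1), np.nan)
            Q = np.where(ns > 0, (df - ts) / np.maximum(ns, 1), np.nan)
        d = _k2p_from_pq(P, Q)
        d = np.atleast_1d(d)
        if np.isnan(d).any():
            bad = [aln.sample_ids[i + 1 + k] for k in np.flatnonzero(np.isnan(d))]
            warnings.warn(
                f"{aln.entity_id}: {len(bad)} pair(s) with sample "
                f"{aln.sample_ids[i]!r} saturated or without comparable sites "
                f"({bad}); set to NaN",
                SaturationWarning,
                stacklevel=2,
            )
        D[i, rest] = D[rest, i] = d
        Pm[i, rest] = Pm[rest, i] = P
        Qm[i, rest] = Qm[rest, i] = Q
        sites[i, rest] = sites[rest, i] = ns
    return StrainDistanceSet(
        entity_id=aln.entity_id,
        sample_ids=aln.sample_ids,
        D=D,
        valid_sites=sites,
        P=Pm,
        Q=Qm,
    )


def median_normalize(
    dset: StrainDistanceSet, normalizer: float | None = None
) -> StrainDistanceSet:
    """Divide the distance matrix by a per-entity normalisation median.

    When ``normalizer`` is None the median of all finite off-diagonal
    distances is used.  Callers that normalise by the within-individual
    median (the convention for strain-identity cutpoints) pass it explicitly;
    see :func:`virotrace.transmission.within_individual_median`.  A zero or
    undefined normaliser raises: the entity carries no usable signal and must
    be excluded upstream.
    """
    if normalizer is None:
        off = dset.D[~np.eye(len(dset.sample_ids), dtype=bool)]
        off = off[np.isfinite(off)]
        if off.size == 0:
            raise ValueError(f"{dset.entity_id}: no finite distances to normalise by")
        normalizer = float(np.median(off))
    if not np.isfinite(normalizer) or normalizer <= 0:
        raise ValueError(
            f"{dset.entity_id}: normaliser must be finite and > 0, got {normalizer}"
        )
    dset.D_norm = dset.D / normalizer
    dset.normalizer = float(normalizer)
    return dset
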