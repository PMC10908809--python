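"""Longitudinal virome/bacteriome summary statistics.

Alpha diversity (Shannon, natural log), Bray-Curtis dissimilarity, retention
of baseline entities at later timepoints, the persistent/transient virome
partition (an entity present in >=75% of an individual's samples belongs to
the personal persistent virome, PPV; the rest form the transiently detected
virome, TDV), the per-sample abundance fraction of temperate phages, and
bootstrap percentile confidence intervals for means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "shannon",
    "bray_curtis",
    "RetentionResult",
    "retention_metrics",
    "PersistencePartition",
    "persistence_partition",
    "temperate_fraction",
    "bootstrap_ci",
]


def shannon(abundances) -> float:
    """Shannon diversity index H = -sum p_i ln p_i (nats), zeros skipped."""
    x = np.asarray(abundances, dtype=float)
    if (x < 0).any():
        raise ValueError("abundances must be non-negative")
    total = x.sum()
    if total <= 0:
        raise ValueError("cannot compute Shannon diversity of an all-zero vector")
    return float(stats.entropy(x / total))


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y), in [0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("abundances must be non-negative")
    denom = (x + y).sum()
    if denom == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero vectors")
    return float(np.abs(x - y).sum() / denom)


@dataclass
class RetentionResult:
    """Retention of baseline entities in a later sample of the same subject.

    ``pct_of_richness`` is the share of the *later* sample's richness made up
    of entities already present at baseline; ``cum_rel_abund`` is the share
    of the later sample's abundance those retained entities carry.
    """

    subject_id: str
    baseline_label: str
    later_label: str
    n_retained: int
    pct_of_richness: float
    cum_rel_abund: float


def retention_metrics(
    baseline: pd.Series,
    later: pd.Series,
    subject_id: str = "",
    baseline_label: str = "",
    later_label: str = "",
) -> RetentionResult:
    """Presence is value > 0 (abundances are breadth-filtered upstream)."""
    baseline, later = baseline.align(later, fill_value=0.0)
    present_base = set(baseline.index[baseline > 0])
    present_later = later.index[later > 0]
    if len(present_later) == 0:
        raise ValueError(f"later sample {later_label!r} has no entities present")
    retained = [e for e in present_later if e in present_base]
    total = float(later[present_later].sum())
    return RetentionResult(
        subject_id=subject_id,
        baseline_label=baseline_label,
        later_label=later_label,
        n_retained=len(retained),
        pct_of_richness=100.0 * len(retained) / len(present_later),
        cum_rel_abund=100.0 * float(later[retained].sum()) / total,
    )


@dataclass
class PersistencePartition:
    subject_id: str
    ppv_ids: list[str]
    tdv_ids: list[str]


def persistence_partition(
    presence: pd.DataFrame,
    subject_id: str = "",
    threshold: float = 0.75,
    min_samples: int = 3,
) -> PersistencePartition | None:
    """Partition one subject's ever-present entities into PPV and TDV.

    ``presence`` is an entity x sample table of that subject (abundances or
    booleans; presence is value > 0).  An entity joins the PPV when its
    presence fraction is >= ``threshold`` (so 3 of 4 samples makes the 75%
    boundary).  Subjects with fewer than ``min_samples`` samples are skipped
    with a warning (returns None).
    """
    if presence.shape[1] < min_samples:
        warnings.warn(
            f"subject {subject_id!r}: only {presence.shape[1]} sample(s), "
            f"fewer than min_samples={min_samples}; skipped",
            stacklevel=2,
        )
        return None
    mask = presence.to_numpy() > 0
    frac = mask.mean(axis=1)
    ever = mask.any(axis=1)
    ids = np.asarray(presence.index)
    ppv = ids[(frac >= threshold) & ever].tolist()
    tdv = ids[(frac < threshold) & ever].tolist()
    assert not set(ppv) & set(tdv) and set(ppv) | set(tdv) == set(ids[ever])
    return PersistencePartition(subject_id=subject_id, ppv_ids=ppv, tdv_ids=tdv)


def temperate_fraction(matrix: pd.DataFrame, lifestyle: pd.Series) -> pd.Series:
    """Per-sample fraction of total abundance carried by temperate phages."""
    missing = sorted(set(matrix.index) - set(lifestyle.index))
    if missing:
        raise ValueError(f"lifestyle labels missing for entities: {missing[:5]}")
    totals = matrix.sum(axis=0)
    if (totals == 0).any():
        bad = totals.index[totals == 0].tolist()
        raise ValueError(f"sample(s) with zero total abundance: {bad[:5]}")
    temp = lifestyle.loc[matrix.index] == "temperate"
    return matrix.loc[temp.values].sum(axis=0) / totals


def bootstrap_ci(
    values, n_boot: int = 1000, seed: int | np.random.Generator = 0
) -> tuple[float, float]:
    """Percentile bootstrap 95% CI for the mean.

    Resamples with replacement ``n_boot`` times and returns the empirical
    0.025/0.975 quantiles of the replicate means (linear interpolation).
    Reproducible given the seed.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("cannot bootstrap an empty vector")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    means = x[idx].mean(axis=1)
    lo, hi = np.quantile(means, [0.025, 0.975])
    return float(lo), float(hi)
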