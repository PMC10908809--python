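"""Phage-host co-transmission linkage.

For each virus-bacterium pair, sharing calls are compared over *concurrent*
samples — (individual, timepoint) units where both the viral and the
bacterial strain were reconstructed (VLP metaviromes take priority over MGS
when both exist for a unit; bacterial strains come from total metagenomes).
Three statistics:

* a partial Mantel correlation between the binarised distance matrices
  (0 = shared strain, 1 = different), controlling for a same-individual
  indicator matrix so longitudinal resampling of one person does not
  masquerade as co-transmission (mothers and their infants count as
  different individuals);
* "non-random linkage" Δ = f_obs − f_exp, the observed frequency of joint
  virus+bacterium sharing minus the product of the marginal sharing
  frequencies, with a chi-squared (no continuity correction) test of
  independence;
* a one-sided Fisher comparison of co-transmission frequency between true
  virus-host pairs and random virus-bacterium pairs.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConcurrentSubset",
    "build_concurrent_subset",
    "partial_mantel",
    "nonrandom_linkage",
    "host_vs_random_enrichment",
    "LinkageResult",
    "analyze_pair",
]


@dataclass
class ConcurrentSubset:
    """Binarised sharing matrices of one virus-bacterium pair over the
    concurrent sample units, plus the same-individual control matrix.

    Entries of ``M_v``/``M_b`` are 0 for a strain-sharing event and 1 for
    different strains; ``C`` is 0 for two units from the same individual and
    1 otherwise.
    """

    virus_id: str
    bacterium_id: str
    units: list[tuple[str, str]]     # (individual_id, timepoint_label)
    M_v: np.ndarray
    M_b: np.ndarray
    C: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.units)
        for name in ("M_v", "M_b", "C"):
            m = getattr(self, name)
            if m.shape != (n, n):
                raise ValueError(f"{name} shape mismatch")
            if not np.allclose(m, m.T, equal_nan=True):
                raise ValueError(f"{name} must be symmetric")


_SOURCE_PRIORITY = {"VLP": 0, "MGS": 1, "TOTAL": 2}


def _units_for(sample_ids, metadata, sources):
    """Map (individual, timepoint) -> chosen sample id, VLP first."""
    meta = metadata.set_index("sample_id")
    chosen: dict[tuple[str, str], str] = {}
    for sid in sample_ids:
        row = meta.loc[sid]
        if row["source"] not in sources:
            continue
        key = (row["individual_id"], row["timepoint_label"])
        if key not in chosen or (
            _SOURCE_PRIORITY[row["source"]]
            < _SOURCE_PRIORITY[meta.loc[chosen[key], "source"]]
        ):
            chosen[key] = sid
    return chosen


def build_concurrent_subset(
    virus_events: np.ndarray,
    virus_samples: list[str],
    bacterium_events: np.ndarray,
    bacterium_samples: list[str],
    metadata: pd.DataFrame,
    virus_id: str = "",
    bacterium_id: str = "",
    min_units: int = 4,
) -> ConcurrentSubset | None:
    """Intersect the sample sets of a virus and a bacterium into concurrent
    units and binarise their sharing calls.

    ``*_events`` are the binary sharing matrices from
    :func:`virotrace.transmission.call_sharing_events` (1 = shared); here
    they are flipped to the 0 = shared convention of the linkage statistics.
    Viral strains may come from VLP or MGS metaviromes (VLP preferred per
    unit); bacterial strains from total metagenomes only.  Pairs with fewer
    than ``min_units`` concurrent units are skipped (returns None) — a
    Mantel test on 3 units is meaningless.
    """
    v_units = _units_for(virus_samples, metadata, sources=("VLP", "MGS"))
    b_units = _units_for(bacterium_samples, metadata, sources=("TOTAL",))
    units = sorted(set(v_units) & set(b_units))
    if len(units) < min_units:
        return None
    vi = [virus_samples.index(v_units[u]) for u in units]
    bi = [bacterium_samples.index(b_units[u]) for u in units]
    M_v = 1.0 - virus_events[np.ix_(vi, vi)]
    M_b = 1.0 - bacterium_events[np.ix_(bi, bi)]
    np.fill_diagonal(M_v, 0.0)
    np.fill_diagonal(M_b, 0.0)
    inds = np.array([u[0] for u in units])
    C = (inds[:, None] != inds[None, :]).astype(float)
    return ConcurrentSubset(
        virus_id=virus_id, bacterium_id=bacterium_id, units=units,
        M_v=M_v, M_b=M_b, C=C,
    )


def _upper(m: np.ndarray) -> np.ndarray:
    return m[np.triu_indices(m.shape[0], k=1)]


def _pearson(x, y):
    sx, sy = np.std(x), np.std(y)
    if sx == 0 or sy == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def _partial_r(rvb, rvc, rbc):
    denom = (1.0 - rvc**2) * (1.0 - rbc**2)
    if denom <= 0:
        return np.nan
    return (rvb - rvc * rbc) / np.sqrt(denom)


def partial_mantel(
    M_v: np.ndarray,
    M_b: np.ndarray,
    C: np.ndarray | None,
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
    method: str = "auto",
    max_exact: int = 5040,
) -> tuple[float, float, bool]:
    """Partial Mantel correlation of M_v and M_b given C, permutation p.

    Pearson correlation on the vectorised upper triangles with the standard
    residual formula r_M = (r_vb − r_vc·r_bc)/sqrt((1−r_vc²)(1−r_bc²));
    the null simultaneously permutes rows and columns of ``M_v``, one-sided
    for positive association.  Small problems (``method='exact'``, or
    ``'auto'`` when n! <= ``max_exact``) enumerate all n! permutations and
    p = #{r_perm >= r_obs}/n! (the identity included); otherwise ``n_perm``
    Monte-Carlo permutations give p = (1 + #{r_perm >= r_obs})/(n_perm + 1).
    When ``M_v`` and ``M_b`` are collinear (|r|=1, the partial correlation
    is degenerate), a simple Mantel test is used instead
    (``used_partial=False``); ``C=None`` requests a simple Mantel directly.
    A matrix that is constant, or collinear with ``C``, makes the statistic
    undefined and raises ValueError (callers skip the pair).
    """
    n = M_v.shape[0]
    if n < 4:
        raise ValueError("need >= 4 samples for a Mantel test")
    if method not in ("auto", "exact", "mc"):
        raise ValueError("method must be 'auto', 'exact' or 'mc'")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    v = _upper(M_v)
    b = _upper(M_b)
    if np.std(v) == 0 or np.std(b) == 0:
        raise ValueError("constant distance matrix; Mantel statistic undefined")

    use_partial = C is not None
    if use_partial:
        c = _upper(C)
        if np.std(c) == 0:
            use_partial = False
        else:
            rvc = _pearson(v, c)
            rbc = _pearson(b, c)
            if abs(rvc) >= 1.0 - 1e-12 or abs(rbc) >= 1.0 - 1e-12:
                raise ValueError(
                    "distance matrix collinear with the control matrix"
                )
    rvb = _pearson(v, b)
    if use_partial and abs(rvb) >= 1.0 - 1e-12:
        # identical sharing patterns: partial correlation degenerates, fall
        # back to the simple Mantel statistic
        use_partial = False

    iu = np.triu_indices(n, k=1)

    def statistic(perm):
        Mp = M_v[np.ix_(perm, perm)]
        vp = Mp[iu]
        r = _pearson(vp, b)
        if not use_partial:
            return r
        rvc_p = _pearson(vp, c)
        return _partial_r(r, rvc_p, rbc)

    ident = np.arange(n)
    r_obs = statistic(ident)
    if np.isnan(r_obs):
        raise ValueError("Mantel statistic undefined (degenerate correlation)")
    exact = method == "exact" or (
        method == "auto" and math.factorial(n) <= max_exact
    )
    # permutations with an undefined statistic (a permuted matrix collinear
    # with the control) carry no information and are excluded from the null
    if exact:
        hits = valid = 0
        for perm in itertools.permutations(range(n)):
            r_p = statistic(np.asarray(perm))
            if np.isnan(r_p):
                continue
            valid += 1
            hits += r_p >= r_obs - 1e-12
        p = hits / valid
    else:
        hits = valid = 0
        for _ in range(n_perm):
            r_p = statistic(rng.permutation(n))
            if np.isnan(r_p):
                continue
            valid += 1
            hits += r_p >= r_obs - 1e-12
        p = (1 + hits) / (valid + 1)
    return float(r_obs), float(p), use_partial


def nonrandom_linkage(M_v: np.ndarray, M_b: np.ndarray) -> tuple[float, float]:
    """Non-random linkage Δ = f_obs − f_exp over unordered sample pairs.

    f_obs is the fraction of pairs where both the virus and the bacterium
    share a strain (matrix entry 0); f_exp the product of the marginal
    sharing fractions.  p comes from a chi-squared test of independence on
    the 2x2 (virus shared x bacterium shared) table without continuity
    correction; a degenerate margin (all shared or none) leaves Δ defined
    but p = 1 with a warning.
    """
    sv = _upper(M_v) == 0
    sb = _upper(M_b) == 0
    if sv.size == 0:
        raise ValueError("need >= 1 unordered sample pair")
    f_obs = float((sv & sb).mean())
    f_exp = float(sv.mean() * sb.mean())
    delta = f_obs - f_exp
    table = np.array([
        [int((sv & sb).sum()), int((sv & ~sb).sum())],
        [int((~sv & sb).sum()), int((~sv & ~sb).sum())],
    ])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        warnings.warn(
            "degenerate margin in linkage table; chi-squared undefined, p = 1",
            stacklevel=2,
        )
        return delta, 1.0
    if (stats.contingency.expected_freq(table) < 5).any():
        warnings.warn(
            "expected cell count < 5 in linkage table; chi-squared "
            "approximation is rough",
            stacklevel=2,
        )
    _, p, _, _ = stats.chi2_contingency(table, correction=False)
    return delta, float(p)


def host_vs_random_enrichment(host_flags, random_flags) -> float:
    """One-sided Fisher: virus-host pairs are co-transmitted more often than
    random virus-bacterium pairs.  Flags are booleans (pair classified
    co-transmitted or not).  An empty class gives p = 1 with a warning."""
    host = np.asarray(host_flags, dtype=bool)
    rand = np.asarray(random_flags, dtype=bool)
    if host.size == 0 or rand.size == 0:
        warnings.warn("empty pair class; p set to 1", stacklevel=2)
        return 1.0
    table = [
        [int(host.sum()), int(host.size - host.sum())],
        [int(rand.sum()), int(rand.size - rand.sum())],
    ]
    _, p = stats.fisher_exact(table, alternative="greater")
    return float(p)


@dataclass
class LinkageResult:
    pair_id: str
    virus_id: str
    bacterium_id: str
    mantel_r: float
    p_mantel: float
    used_partial: bool
    nonrandom_linkage: float
    p_chi2: float
    n_units: int
    n_pairs: int
    status: str   # ok | collinear_skipped | too_few_units


def analyze_pair(
    subset: ConcurrentSubset | None,
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
    virus_id: str = "",
    bacterium_id: str = "",
) -> LinkageResult:
    """Partial Mantel + non-random linkage for one virus-bacterium pair."""
    pair_id = f"{virus_id or (subset.virus_id if subset else '?')}~" \
              f"{bacterium_id or (subset.bacterium_id if subset else '?')}"
    if subset is None:
        return LinkageResult(
            pair_id=pair_id, virus_id=virus_id, bacterium_id=bacterium_id,
            mantel_r=float("nan"), p_mantel=float("nan"), used_partial=False,
            nonrandom_linkage=float("nan"), p_chi2=float("nan"),
            n_units=0, n_pairs=0, status="too_few_units",
        )
    n = len(subset.units)
    delta, p_chi2 = nonrandom_linkage(subset.M_v, subset.M_b)
    try:
        r, p, used_partial = partial_mantel(
            subset.M_v, subset.M_b, subset.C, n_perm=n_perm, seed=seed
        )
        status = "ok"
    except ValueError:
        r, p, used_partial = float("nan"), float("nan"), False
        status = "collinear_skipped"
    return LinkageResult(
        pair_id=f"{subset.virus_id}~{subset.bacterium_id}",
        virus_id=subset.virus_id,
        bacterium_id=subset.bacterium_id,
        mantel_r=r, p_mantel=p, used_partial=used_partial,
        nonrandom_linkage=delta, p_chi2=p_chi2,
        n_units=n, n_pairs=n * (n - 1) // 2,
        status=status,
    )
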