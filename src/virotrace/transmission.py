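"""Strain-level mother-to-infant transmission inference.

Per entity (vOTU or bacterial species), the analysis asks whether strains in
related mother-infant sample pairs are genetically closer than strains in
unrelated (cross-family) mother-infant pairs, derives a strain-identity
cutpoint from the within-individual strain drift, calls strain-sharing
events, and tests their enrichment in related pairs and their timing
relative to birth.

The distance comparison is a one-sided Wilcoxon rank-sum statistic whose
significance comes from a permutation of the related/unrelated labels over
pairs — the group sizes are highly unequal, so the permutation null respects
them exactly.  Cutpoints follow the kernel-smoothed Youden approach on
median-normalised distances, with an empirical-FDR fallback (5th percentile
of the unrelated distances) when the Youden threshold would admit more than
5% of unrelated pairs.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .distances import StrainDistanceSet, median_normalize
from .synthetic import PRE_BIRTH

__all__ = [
    "label_pairs",
    "related_unrelated_permutation_test",
    "bh_adjust",
    "CutpointResult",
    "estimate_cutpoint",
    "call_sharing_events",
    "sharing_enrichment_fisher",
    "prepost_birth_comparison",
    "within_individual_median",
    "analyze_transmission",
]


def label_pairs(sample_ids: list[str], metadata: pd.DataFrame) -> pd.DataFrame:
    """Label every unordered sample pair by relation and maternal birth class.

    Relations: ``within_individual`` (longitudinal pair of one person),
    ``related`` (mother-infant pair of one family), ``unrelated``
    (mother-infant pair across families); any other combination (e.g.
    mother-mother or twin-twin pairs) is labelled ``other`` and excluded from
    the transmission tests.  ``birth_class`` classifies the maternal sample
    of mother-infant pairs as ``pre_birth`` (pregnancy/birth timepoints) or
    ``post_birth``.
    """
    meta = metadata.set_index("sample_id")
    missing = [s for s in sample_ids if s not in meta.index]
    if missing:
        raise ValueError(f"samples absent from metadata: {missing[:5]}")
    rows = []
    for a, b in itertools.combinations(range(len(sample_ids)), 2):
        sa, sb = meta.loc[sample_ids[a]], meta.loc[sample_ids[b]]
        birth_class = "NA"
        if sa["individual_id"] == sb["individual_id"]:
            relation = "within_individual"
        elif {sa["role"], sb["role"]} == {"mother", "infant"}:
            relation = (
                "related" if sa["family_id"] == sb["family_id"] else "unrelated"
            )
            mother = sa if sa["role"] == "mother" else sb
            birth_class = (
                "pre_birth" if mother["timepoint_label"] in PRE_BIRTH
                else "post_birth"
            )
        else:
            relation = "other"
        rows.append({
            "i": a, "j": b,
            "sample_i": sample_ids[a], "sample_j": sample_ids[b],
            "relation": relation, "birth_class": birth_class,
        })
    return pd.DataFrame(rows)


def _rank_sum_observed(related: np.ndarray, unrelated: np.ndarray) -> tuple:
    pooled = np.concatenate([related, unrelated])
    ranks = stats.rankdata(pooled)
    return float(ranks[: related.size].sum()), ranks


def related_unrelated_permutation_test(
    related,
    unrelated,
    n_iter: int = 1000,
    seed: int | np.random.Generator = 0,
    method: str = "auto",
    max_exact: int = 200_000,
) -> float:
    """Permutation p-value for "related distances are smaller".

    The observed statistic is the Wilcoxon rank-sum of the related group
    (small = related distances rank low).  The null permutes the
    related/unrelated labels over pairs.  With ``method='exact'`` (or
    ``'auto'`` when the number of label assignments is at most
    ``max_exact``), all C(n, n_related) assignments are enumerated and
    p = #{S_perm <= S_obs}/N; otherwise ``n_iter`` Monte-Carlo draws give
    p = (1 + #{S_perm <= S_obs})/(n_iter + 1).  Deterministic given the seed.
    """
    related = np.asarray(related, dtype=float)
    unrelated = np.asarray(unrelated, dtype=float)
    related = related[np.isfinite(related)]
    unrelated = unrelated[np.isfinite(unrelated)]
    if related.size == 0 or unrelated.size == 0:
        raise ValueError("need >=1 finite distance in each group")
    obs, ranks = _rank_sum_observed(related, unrelated)
    n, n1 = ranks.size, related.size
    n_total = math.comb(n, n1)
    if method not in ("auto", "exact", "mc"):
        raise ValueError("method must be 'auto', 'exact' or 'mc'")
    exact = method == "exact" or (method == "auto" and n_total <= max_exact)
    if exact:
        hits = sum(
            1
            for combo in itertools.combinations(range(n), n1)
            if ranks[list(combo)].sum() <= obs + 1e-9
        )
        return hits / n_total
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    stats_null = np.empty(n_iter)
    # argpartition of uniform noise = a uniformly random n1-subset per row
    block = 250
    for start in range(0, n_iter, block):
        k = min(block, n_iter - start)
        noise = rng.random((k, n))
        idx = np.argpartition(noise, n1 - 1, axis=1)[:, :n1]
        stats_null[start:start + k] = ranks[idx].sum(axis=1)
    hits = int((stats_null <= obs + 1e-9).sum())
    return (1 + hits) / (n_iter + 1)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class CutpointResult:
    """Strain-identity cutpoint on the median-normalised distance scale."""

    entity_id: str
    threshold: float
    method: str                 # youden_kernel | empirical_fdr
    youden_J: float             # empirical sensitivity + specificity - 1
    unrelated_admit_rate: float


def estimate_cutpoint(
    within_norm,
    unrelated_norm,
    entity_id: str = "",
    fdr_quantile: float = 0.05,
    youden_gate: bool = False,
    grid_size: int = 512,
) -> CutpointResult:
    """Kernel-Youden strain-identity cutpoint with empirical-FDR fallback.

    Within-individual normalised distances are the positives (a strain below
    the cutpoint is "the same"), unrelated-pair distances the negatives.
    Gaussian KDEs (Silverman bandwidth) of both groups are evaluated on a
    ``grid_size``-point grid over the pooled range and the threshold
    maximises the smoothed Youden index J(t) = TPR(t) + TNR(t) - 1, taking
    the middle of any plateau.  If the fraction of unrelated pairs admitted
    below that threshold exceeds ``fdr_quantile``, the threshold is replaced
    by the ``fdr_quantile`` quantile (linear interpolation) of the unrelated
    distances (method ``empirical_fdr``).  Setting ``youden_gate=True``
    applies the fallback whenever the empirical J exceeds ``fdr_quantile``
    instead (an alternative reading of the rule).
    """
    pos = np.asarray(within_norm, dtype=float)
    neg = np.asarray(unrelated_norm, dtype=float)
    pos = pos[np.isfinite(pos)]
    neg = neg[np.isfinite(neg)]
    if pos.size < 3 or neg.size < 3:
        raise ValueError(
            f"{entity_id}: need >=3 finite distances per group "
            f"(got {pos.size} within, {neg.size} unrelated)"
        )
    if np.std(pos) == 0 or np.std(neg) == 0:
        warnings.warn(
            f"{entity_id}: degenerate (zero-variance) group; falling back to "
            "the midpoint between the groups",
            stacklevel=2,
        )
        threshold = 0.5 * (pos.max() + neg.min())
    else:
        kde_pos = stats.gaussian_kde(pos, bw_method="silverman")
        kde_neg = stats.gaussian_kde(neg, bw_method="silverman")
        lo = min(pos.min(), neg.min())
        hi = max(pos.max(), neg.max())
        grid = np.linspace(lo, hi, grid_size)
        f_pos = np.array([kde_pos.integrate_box_1d(-np.inf, t) for t in grid])
        f_neg = np.array([kde_neg.integrate_box_1d(-np.inf, t) for t in grid])
        J = f_pos - f_neg
        near_max = np.flatnonzero(J >= J.max() - 1e-9)
        threshold = float(grid[near_max[(len(near_max) - 1) // 2]])

    def empirical(thr):
        J_emp = float((pos < thr).mean() - (neg < thr).mean())
        admit = float((neg < thr).mean())
        return J_emp, admit

    youden_J, admit = empirical(threshold)
    method = "youden_kernel"
    trigger = youden_J > fdr_quantile if youden_gate else admit > fdr_quantile
    if trigger:
        threshold = float(np.quantile(neg, fdr_quantile))
        method = "empirical_fdr"
        youden_J, admit = empirical(threshold)
    return CutpointResult(
        entity_id=entity_id,
        threshold=threshold,
        method=method,
        youden_J=youden_J,
        unrelated_admit_rate=admit,
    )


def call_sharing_events(D_norm: np.ndarray, threshold: float) -> np.ndarray:
    """Binary strain-sharing matrix: 1 where D_norm < threshold (strict).

    Normalised distances above the cutpoint mean different strains; below it,
    a strain-sharing event.  A pair exactly at the threshold is not shared
    (the rule is strict on both sides, so ties resolve conservatively).
    NaN distances stay NaN (missing, excluded downstream).
    """
    if not np.isfinite(threshold) or threshold <= 0:
        raise ValueError(f"threshold must be finite and > 0, got {threshold}")
    D_norm = np.asarray(D_norm, dtype=float)
    events = np.where(np.isnan(D_norm), np.nan, (D_norm < threshold).astype(float))
    return events


def _pair_events(events: np.ndarray, labels: pd.DataFrame, relation: str,
                 birth_class: str | None = None) -> np.ndarray:
    sel = labels["relation"] == relation
    if birth_class is not None:
        sel &= labels["birth_class"] == birth_class
    vals = events[labels.loc[sel, "i"], labels.loc[sel, "j"]]
    return vals[np.isfinite(vals)]


def sharing_enrichment_fisher(events: np.ndarray, labels: pd.DataFrame
                              ) -> tuple[float, dict]:
    """One-sided Fisher test: related pairs share strains more often.

    Returns (p, counts) where counts holds the 2x2 table margins.  An empty
    margin (no related or no unrelated pairs with a call) gives p = 1 with a
    warning.
    """
    rel = _pair_events(events, labels, "related")
    unrel = _pair_events(events, labels, "unrelated")
    counts = {
        "n_related": rel.size,
        "n_unrelated": unrel.size,
        "related_shared": int(rel.sum()),
        "unrelated_shared": int(unrel.sum()),
    }
    if rel.size == 0 or unrel.size == 0:
        warnings.warn("empty margin in sharing table; p set to 1", stacklevel=2)
        return 1.0, counts
    table = [
        [counts["related_shared"], rel.size - counts["related_shared"]],
        [counts["unrelated_shared"], unrel.size - counts["unrelated_shared"]],
    ]
    _, p = stats.fisher_exact(table, alternative="greater")
    return float(p), counts


def prepost_birth_comparison(events: np.ndarray, labels: pd.DataFrame
                             ) -> float:
    """One-sided Fisher test: related pairs share more with post-birth
    maternal samples than with pre-birth ones.  Returns NaN (entity skipped)
    when either birth class has no related pairs."""
    post = _pair_events(events, labels, "related", "post_birth")
    pre = _pair_events(events, labels, "related", "pre_birth")
    if post.size == 0 or pre.size == 0:
        warnings.warn(
            "a maternal birth class has no pairs; pre/post comparison skipped",
            stacklevel=2,
        )
        return float("nan")
    table = [
        [int(post.sum()), post.size - int(post.sum())],
        [int(pre.sum()), pre.size - int(pre.sum())],
    ]
    _, p = stats.fisher_exact(table, alternative="greater")
    return float(p)


def within_individual_median(dset: StrainDistanceSet, labels: pd.DataFrame
                             ) -> float:
    """Normalisation median for one entity.

    The median of finite within-individual (longitudinal) distances, pooling
    mothers and infants; when no within-individual pair exists, the median of
    all finite off-diagonal distances stands in.
    """
    within = labels[labels["relation"] == "within_individual"]
    vals = dset.D[within["i"], within["j"]]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        off = dset.D[np.triu_indices(len(dset.sample_ids), k=1)]
        vals = off[np.isfinite(off)]
    if vals.size == 0:
        raise ValueError(f"{dset.entity_id}: no finite distances to normalise by")
    return float(np.median(vals))


@dataclass
class TransmissionResult:
    entity_id: str
    p_perm: float
    q: float
    n_related: int
    n_unrelated: int
    share_rate_related: float
    share_rate_unrelated: float
    p_fisher: float
    q_fisher: float
    p_prepost: float
    n_events: int
    threshold: float
    cutpoint_method: str


def analyze_transmission(
    distance_sets: dict[str, StrainDistanceSet],
    metadata: pd.DataFrame,
    n_iter: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Full per-entity transmission analysis over a set of distance matrices.

    Returns the per-entity result table (permutation p and BH q for the
    distance comparison; sharing rates, Fisher enrichment p/q, pre/post-birth
    p; events count; the cutpoint used) and the per-entity binary sharing
    matrices.  Entities without both related and unrelated pairs, or without
    enough distances to place a cutpoint, are skipped with a warning.
    """
    rows: list[dict] = []
    all_events: dict[str, np.ndarray] = {}
    rng = np.random.default_rng(seed)
    for entity_id in sorted(distance_sets):
        dset = distance_sets[entity_id]
        labels = label_pairs(dset.sample_ids, metadata)
        rel = dset.D[labels.loc[labels["relation"] == "related", "i"],
                     labels.loc[labels["relation"] == "related", "j"]]
        unrel = dset.D[labels.loc[labels["relation"] == "unrelated", "i"],
                       labels.loc[labels["relation"] == "unrelated", "j"]]
        rel = rel[np.isfinite(rel)]
        unrel = unrel[np.isfinite(unrel)]
        if rel.size == 0 or unrel.size == 0:
            warnings.warn(
                f"{entity_id}: missing related or unrelated pairs; skipped",
                stacklevel=2,
            )
            continue
        p_perm = related_unrelated_permutation_test(
            rel, unrel, n_iter=n_iter, seed=rng.spawn(1)[0]
        )
        normalizer = within_individual_median(dset, labels)
        median_normalize(dset, normalizer)
        within = labels[labels["relation"] == "within_individual"]
        unrelated = labels[labels["relation"] == "unrelated"]
        within_norm = dset.D_norm[within["i"], within["j"]]
        unrel_norm = dset.D_norm[unrelated["i"], unrelated["j"]]
        try:
            cut = estimate_cutpoint(within_norm, unrel_norm, entity_id=entity_id)
        except ValueError as err:
            warnings.warn(f"cutpoint unavailable: {err}; entity skipped",
                          stacklevel=2)
            continue
        events = call_sharing_events(dset.D_norm, cut.threshold)
        np.fill_diagonal(events, np.nan)
        all_events[entity_id] = events
        p_fisher, counts = sharing_enrichment_fisher(events, labels)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p_prepost = prepost_birth_comparison(events, labels)
        rows.append({
            "entity_id": entity_id,
            "p_perm": p_perm,
            "n_related": counts["n_related"],
            "n_unrelated": counts["n_unrelated"],
            "share_rate_related": (
                counts["related_shared"] / counts["n_related"]
                if counts["n_related"] else float("nan")
            ),
            "share_rate_unrelated": (
                counts["unrelated_shared"] / counts["n_unrelated"]
                if counts["n_unrelated"] else float("nan")
            ),
            "p_fisher": p_fisher,
            "p_prepost": p_prepost,
            "n_events": counts["related_shared"],
            "threshold": cut.threshold,
            "cutpoint_method": cut.method,
        })
    results = pd.DataFrame(rows)
    if not results.empty:
        results["q"] = bh_adjust(results["p_perm"])
        results["q_fisher"] = bh_adjust(results["p_fisher"])
        results["transmitted_call"] = results["q"] < alpha
    return results, all_events
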