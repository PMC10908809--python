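"""Transmission inference: permutation test, cutpoints, sharing calls."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from virotrace.transmission import (
    bh_adjust,
    call_sharing_events,
    estimate_cutpoint,
    label_pairs,
    prepost_birth_comparison,
    related_unrelated_permutation_test,
    sharing_enrichment_fisher,
    within_individual_median,
)


# ---------------------------------------------------------------------------
# independent oracle: exhaustive label enumeration with its own rank code
def _avg_rank(v, pooled):
    less = sum(1 for w in pooled if w < v)
    ties = sum(1 for w in pooled if w == v)
    return less + (1 + ties) / 2


def brute_force_perm_p(related, unrelated):
    pooled = list(related) + list(unrelated)
    n1 = len(related)
    ranks = [_avg_rank(v, pooled) for v in pooled]
    obs = sum(ranks[:n1])
    combos = list(itertools.combinations(range(len(pooled)), n1))
    hits = sum(1 for c in combos if sum(ranks[i] for i in c) <= obs + 1e-9)
    return hits / len(combos)


def _meta(rows):
    return pd.DataFrame(rows, columns=[
        "sample_id", "individual_id", "family_id", "role", "timepoint_label",
        "age_days", "source", "library_size", "dna_conc",
    ])


class TestLabelPairs:
    def test_relations_and_birth_classes(self):
        meta = _meta([
            ("m1a", "M1", "F1", "mother", "P7", -84, "VLP", 10, 1.0),
            ("m1b", "M1", "F1", "mother", "M1", 30, "VLP", 10, 1.0),
            ("i1", "I1", "F1", "infant", "M1", 30, "VLP", 10, 1.0),
            ("m2", "M2", "F2", "mother", "M3", 91, "VLP", 10, 1.0),
        ])
        lab = label_pairs(["m1a", "m1b", "i1", "m2"], meta).set_index(
            ["sample_i", "sample_j"]
        )
        assert lab.loc[("m1a", "m1b"), "relation"] == "within_individual"
        assert lab.loc[("m1a", "i1"), "relation"] == "related"
        assert lab.loc[("m1a", "i1"), "birth_class"] == "pre_birth"
        assert lab.loc[("m1b", "i1"), "birth_class"] == "post_birth"
        assert lab.loc[("i1", "m2"), "relation"] == "unrelated"
        assert lab.loc[("m1a", "m2"), "relation"] == "other"

    def test_unknown_sample_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            label_pairs(["nope"], _meta([]))


class TestPermutationTest:
    def test_exact_mode_matches_brute_force(self):
        related = [0.1, 0.3]
        unrelated = [0.2, 0.5, 0.4]
        p = related_unrelated_permutation_test(related, unrelated, method="exact")
        assert p == pytest.approx(brute_force_perm_p(related, unrelated))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_exact_mode_matches_brute_force_random_cases(self, seed):
        rng = np.random.default_rng(seed)
        related = rng.random(3)
        unrelated = rng.random(6)
        p = related_unrelated_permutation_test(related, unrelated, method="exact")
        assert p == pytest.approx(brute_force_perm_p(related, unrelated))

    def test_perfect_separation_mc_lower_bound(self):
        related = np.linspace(0.001, 0.01, 8)
        unrelated = np.linspace(0.5, 1.0, 30)
        p = related_unrelated_permutation_test(
            related, unrelated, n_iter=1000, seed=0, method="mc"
        )
        assert p == pytest.approx(1 / 1001)

    def test_ignores_nan_distances(self):
        p1 = related_unrelated_permutation_test(
            [0.1, np.nan], [0.2, 0.3, np.nan, 0.4], method="exact"
        )
        p2 = related_unrelated_permutation_test(
            [0.1], [0.2, 0.3, 0.4], method="exact"
        )
        assert p1 == p2

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            related_unrelated_permutation_test([], [0.1])

    def test_wilcoxon_ordering_consistency(self, rng):
        # the permutation statistic orders cases like scipy's one-sided
        # Mann-Whitney: clearly separated groups get a smaller p than
        # overlapping ones
        rel_far = rng.normal(0.0, 1.0, 10)
        rel_near = rel_far + 4.0
        unrel = rng.normal(5.0, 1.0, 40)
        p_far = related_unrelated_permutation_test(
            rel_far, unrel, n_iter=2000, seed=1, method="mc")
        p_near = related_unrelated_permutation_test(
            rel_near, unrel, n_iter=2000, seed=1, method="mc")
        assert p_far < p_near
        u_far = stats.mannwhitneyu(rel_far, unrel, alternative="less").pvalue
        u_near = stats.mannwhitneyu(rel_near, unrel, alternative="less").pvalue
        assert (p_far < p_near) == (u_far < u_near)


def test_pooled_design_is_never_anticonservative():
    """Pooling all mother-infant pairs makes distances dependent through
    shared samples; the label-permutation test must then under-reject, not
    over-reject."""
    from virotrace.experiments import pooled_typeI_experiment

    res = pooled_typeI_experiment(n_entities=100, seed=3)
    assert res["rejection_rate"] <= 0.07


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_step_up(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_monotone_in_sorted_p(self, rng):
        p = np.sort(rng.random(25)).clip(1e-9, 1.0)
        q = bh_adjust(p)
        assert (np.diff(q) >= -1e-12).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.0, 0.5])


class TestCutpoint:
    def test_perfect_separation_youden(self):
        pos = np.linspace(0.05, 0.2, 10)
        neg = np.linspace(0.8, 2.0, 20)
        cut = estimate_cutpoint(pos, neg)
        assert cut.method == "youden_kernel"
        assert 0.2 < cut.threshold < 0.8
        assert cut.youden_J == 1.0
        assert cut.unrelated_admit_rate == 0.0

    def test_overlap_triggers_empirical_fdr_fallback(self):
        neg = np.round(np.arange(1.0, 2.91, 0.1), 10)  # 20 values 1.0..2.9
        pos = neg - 0.10  # heavy overlap: Youden admits far more than 5%
        cut = estimate_cutpoint(pos, neg)
        assert cut.method == "empirical_fdr"
        # 5th percentile of 20 evenly spaced values under linear interpolation
        assert cut.threshold == pytest.approx(1.095)
        assert cut.unrelated_admit_rate <= 0.05

    def test_degenerate_group_falls_back_to_midpoint(self):
        with pytest.warns(UserWarning, match="degenerate"):
            cut = estimate_cutpoint([0.1] * 5, [1.0, 1.2, 1.4])
        assert cut.threshold == pytest.approx(0.55)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match=">=3"):
            estimate_cutpoint([0.1, 0.2], [1.0, 1.1, 1.2])


class TestSharingCalls:
    def test_tie_at_threshold_not_shared(self):
        D = np.array([[0.0, 0.5], [0.5, 0.0]])
        events = call_sharing_events(D, 0.5)
        assert events[0, 1] == 0.0

    def test_all_zero_distances_all_shared(self):
        D = np.zeros((3, 3))
        assert call_sharing_events(D, 0.5).sum() == 9  # incl. diagonal zeros

    def test_toy_hand_count(self):
        vals = [0.1, 0.4, 0.6, 0.9, 0.2, 0.7]
        D = np.zeros((4, 4))
        it = iter(vals)
        for i in range(4):
            for j in range(i + 1, 4):
                D[i, j] = D[j, i] = next(it)
        events = call_sharing_events(D, 0.5)
        assert np.nansum(np.triu(events, k=1)) == 3

    def test_nan_stays_missing_and_monotone_in_threshold(self):
        D = np.array([[0.0, np.nan], [np.nan, 0.0]])
        assert np.isnan(call_sharing_events(D, 0.5)[0, 1])
        vals = np.random.default_rng(1).random((5, 5))
        D = (vals + vals.T) / 2
        lo = call_sharing_events(D, 0.3)
        hi = call_sharing_events(D, 0.7)
        assert (hi >= lo).all()


class TestFisherTests:
    @staticmethod
    def _labels_events(rel_shared, rel_total, unrel_shared, unrel_total,
                       birth=None):
        n = rel_total + unrel_total
        # one synthetic pair per row of a (n+1)-sample fake matrix
        labels = []
        events = np.full((n + 1, n + 1), np.nan)
        k = 1
        for cls, shared, total in (("related", rel_shared, rel_total),
                                   ("unrelated", unrel_shared, unrel_total)):
            for t in range(total):
                labels.append({
                    "i": 0, "j": k, "relation": cls,
                    "birth_class": (birth[len(labels)] if birth else "NA"),
                })
                events[0, k] = events[k, 0] = 1.0 if t < shared else 0.0
                k += 1
        return events, pd.DataFrame(labels)

    def test_hand_hypergeometric_value(self):
        events, labels = self._labels_events(8, 10, 2, 10)
        p, counts = sharing_enrichment_fisher(events, labels)
        assert p == pytest.approx(2126 / 184756)
        assert counts["related_shared"] == 8

    def test_equal_rates_not_significant(self):
        events, labels = self._labels_events(5, 10, 5, 10)
        p, _ = sharing_enrichment_fisher(events, labels)
        assert p >= 0.5

    def test_no_related_sharing_gives_p_one(self):
        events, labels = self._labels_events(0, 10, 3, 10)
        p, _ = sharing_enrichment_fisher(events, labels)
        assert p == 1.0

    def test_empty_margin_warns_p_one(self):
        events, labels = self._labels_events(2, 4, 0, 0)
        with pytest.warns(UserWarning, match="empty margin"):
            p, _ = sharing_enrichment_fisher(events, labels)
        assert p == 1.0

    def test_prepost_hand_value_and_antisymmetry(self):
        birth = ["post_birth"] * 6 + ["pre_birth"] * 6
        events, labels = self._labels_events(5, 6, 0, 6, birth=birth)
        labels["relation"] = "related"
        p = prepost_birth_comparison(events, labels)
        # hypergeometric tail: P(X>=5), N=12, K=5, n=6 -> 7/924
        assert p == pytest.approx(7 / 924)
        flipped = labels.copy()
        flipped["birth_class"] = flipped["birth_class"].map(
            {"post_birth": "pre_birth", "pre_birth": "post_birth"}
        )
        assert prepost_birth_comparison(events, flipped) > 0.5

    def test_prepost_missing_class_skipped(self):
        events, labels = self._labels_events(2, 4, 0, 0,
                                             birth=["post_birth"] * 4)
        labels["relation"] = "related"
        with pytest.warns(UserWarning, match="skipped"):
            assert math.isnan(prepost_birth_comparison(events, labels))


class TestNormalizer:
    def test_prefers_within_individual_median(self):
        from virotrace.distances import StrainDistanceSet

        D = np.array([
            [0.0, 0.2, 0.8],
            [0.2, 0.0, 0.9],
            [0.8, 0.9, 0.0],
        ])
        dset = StrainDistanceSet("e", ["a", "b", "c"], D,
                                 np.full((3, 3), 10))
        labels = pd.DataFrame([
            {"i": 0, "j": 1, "relation": "within_individual"},
            {"i": 0, "j": 2, "relation": "unrelated"},
            {"i": 1, "j": 2, "relation": "unrelated"},
        ])
        assert within_individual_median(dset, labels) == pytest.approx(0.2)
        labels["relation"] = "unrelated"
        # falls back to the median of all finite distances
        assert within_individual_median(dset, labels) == pytest.approx(0.8)
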