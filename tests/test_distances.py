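"""Kimura 2-parameter distances: closed form, deletion handling, scaling."""

import numpy as np
import pytest

from virotrace.distances import (
    SaturationWarning,
    StrainAlignment,
    k2p_distance,
    median_normalize,
    pairwise_k2p,
    trim_alignment,
)
from virotrace.synthetic import _random_sequence, evolve_sequence


def _seq_with_counts(n, n_ts, n_tv):
    """Pair of length-n sequences with the given transition/transversion
    difference counts."""
    s1 = "A" * n
    s2 = "G" * n_ts + "C" * n_tv + "A" * (n - n_ts - n_tv)
    return s1, s2


class TestK2PDistance:
    def test_identical_sequences_give_exact_zero(self):
        d, P, Q, n = k2p_distance("ACGTACGT", "ACGTACGT")
        assert d == 0.0 and P == 0.0 and Q == 0.0 and n == 8

    def test_closed_form_hand_value(self):
        # P=0.10, Q=0.05 -> d = -1/2 ln(0.75 * sqrt(0.90)) = 0.170181
        s1, s2 = _seq_with_counts(100, 10, 5)
        d, P, Q, n = k2p_distance(s1, s2)
        assert (P, Q, n) == (0.10, 0.05, 100)
        assert d == pytest.approx(0.1701812, abs=1e-6)

    def test_saturation_returns_nan_with_warning(self):
        s1, s2 = _seq_with_counts(100, 50, 0)  # P=0.5, Q=0: log of <=0
        with pytest.warns(SaturationWarning):
            d, P, Q, _ = k2p_distance(s1, s2)
        assert np.isnan(d) and P == 0.5

    def test_ambiguous_sites_excluded(self):
        d, _, _, n = k2p_distance("ACGTN-", "ACGAAC")
        assert n == 4  # N and gap columns dropped
        assert d > 0

    def test_no_comparable_sites_raises(self):
        with pytest.raises(ValueError, match="comparable"):
            k2p_distance("NNN", "ACG")

    def test_monotone_in_P_and_Q(self):
        base = k2p_distance(*_seq_with_counts(1000, 50, 30))[0]
        more_ts = k2p_distance(*_seq_with_counts(1000, 60, 30))[0]
        more_tv = k2p_distance(*_seq_with_counts(1000, 50, 40))[0]
        assert more_ts > base and more_tv > base

    def test_small_distance_limit_is_p_plus_q(self):
        s1, s2 = _seq_with_counts(1000, 1, 1)  # P = Q = 0.001
        d = k2p_distance(s1, s2)[0]
        assert d == pytest.approx(0.002, abs=1e-4)


class TestTrim:
    def test_trims_both_ends(self):
        aln = StrainAlignment("e", {"a": "A" * 1000, "b": "C" * 1000})
        assert trim_alignment(aln, 100).length == 800

    def test_zero_trim_is_identity(self):
        aln = StrainAlignment("e", {"a": "ACGT" * 10, "b": "TGCA" * 10})
        assert trim_alignment(aln, 0).records == aln.records

    def test_too_short_raises(self):
        aln = StrainAlignment("e", {"a": "A" * 150, "b": "C" * 150})
        with pytest.raises(ValueError, match="too short"):
            trim_alignment(aln, 100)


class TestPairwise:
    def test_identical_records_zero_matrix(self):
        aln = StrainAlignment("e", {k: "ACGT" * 25 for k in "abc"})
        ds = pairwise_k2p(aln)
        assert np.allclose(ds.D, 0.0)

    def test_matrix_is_symmetric_with_zero_diagonal(self, rng):
        anc = _random_sequence(2000, rng)
        aln = StrainAlignment("e", {
            f"s{i}": evolve_sequence(anc, 0.05, 2.0, i) for i in range(4)
        })
        ds = pairwise_k2p(aln)
        assert np.array_equal(ds.D, ds.D.T)
        assert np.all(np.diag(ds.D) == 0)

    def test_all_gap_column_changes_nothing(self, rng):
        anc = _random_sequence(500, rng)
        recs = {f"s{i}": evolve_sequence(anc, 0.03, 2.0, i) for i in range(3)}
        base = pairwise_k2p(StrainAlignment("e", recs)).D
        padded = {k: v[:250] + "-" + v[250:] for k, v in recs.items()}
        assert np.allclose(pairwise_k2p(StrainAlignment("e", padded)).D, base)

    def test_planted_distance_recovered(self):
        # off-diagonal ancestor-child distances concentrate on the target
        rng = np.random.default_rng(7)
        anc = _random_sequence(10_000, rng)
        ds = []
        for i in range(50):
            child = evolve_sequence(anc, 0.05, 2.0, 100 + i)
            ds.append(k2p_distance(anc, child)[0])
        se = np.std(ds, ddof=1) / np.sqrt(len(ds))
        assert abs(np.mean(ds) - 0.05) < 3 * se + 1e-12

    def test_matches_external_distance_oracle(self):
        # frozen from ape::dist.dna(model="K80") on this exact alignment
        rng = np.random.default_rng(3)
        anc = _random_sequence(1200, rng)
        aln = StrainAlignment("e", {
            "s1": anc,
            "s2": evolve_sequence(anc, 0.05, 2.0, 1),
            "s3": evolve_sequence(anc, 0.12, 2.0, 2),
        })
        D = pairwise_k2p(aln).D
        expected = np.array([
            [0.0, 0.04554405, 0.10459994],
            [0.04554405, 0.0, 0.14816937],
            [0.10459994, 0.14816937, 0.0],
        ])
        assert np.allclose(D, expected, atol=1e-7)

    def test_complete_deletion_drops_columns_globally(self):
        recs = {"a": "AAAA", "b": "A-AA", "c": "AAAT"}
        pair = pairwise_k2p(StrainAlignment("e", recs), deletion="pairwise")
        comp = pairwise_k2p(StrainAlignment("e", recs), deletion="complete")
        # a-c compare 4 sites pairwise but only 3 after complete deletion
        ia, ic = pair.index_of("a"), pair.index_of("c")
        assert pair.valid_sites[ia, ic] == 4
        assert comp.valid_sites[ia, ic] == 3


class TestMedianNormalize:
    def test_constant_matrix_normalises_to_ones(self):
        D = np.full((3, 3), 2.0)
        np.fill_diagonal(D, 0.0)
        ds = _dset(D)
        median_normalize(ds)
        off = ds.D_norm[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 1.0)

    def test_internal_median_is_scale_invariant(self):
        D = _toy_matrix()
        a = median_normalize(_dset(D)).D_norm
        b = median_normalize(_dset(3.0 * D)).D_norm
        assert np.allclose(a, b)

    def test_toy_hand_division(self):
        # off-diagonal distances 1..6 -> median 3.5
        ds = median_normalize(_dset(_toy_matrix()))
        assert ds.normalizer == pytest.approx(3.5)
        assert ds.D_norm[0, 1] == pytest.approx(1 / 3.5)
        assert ds.D_norm[2, 3] == pytest.approx(6 / 3.5)

    def test_zero_normalizer_rejected(self):
        with pytest.raises(ValueError, match="> 0"):
            median_normalize(_dset(_toy_matrix()), normalizer=0.0)

    def test_nan_propagates(self):
        D = _toy_matrix()
        D[0, 1] = D[1, 0] = np.nan
        ds = median_normalize(_dset(D), normalizer=2.0)
        assert np.isnan(ds.D_norm[0, 1]) and ds.D_norm[0, 2] == pytest.approx(1.0)


def _toy_matrix():
    D = np.zeros((4, 4))
    vals = iter([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    for i in range(4):
        for j in range(i + 1, 4):
            D[i, j] = D[j, i] = next(vals)
    return D


def _dset(D):
    from virotrace.distances import StrainDistanceSet

    n = D.shape[0]
    return StrainDistanceSet(
        entity_id="toy",
        sample_ids=[f"s{i}" for i in range(n)],
        D=D.copy(),
        valid_sites=np.full((n, n), 100),
    )
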