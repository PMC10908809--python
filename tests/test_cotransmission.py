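"""Concurrent subsets, partial Mantel, non-random linkage."""

import itertools

import numpy as np
import pandas as pd
import pytest

from virotrace.cotransmission import (
    build_concurrent_subset,
    host_vs_random_enrichment,
    nonrandom_linkage,
    partial_mantel,
)


def _sym(vals, n):
    m = np.zeros((n, n))
    it = iter(vals)
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = next(it)
    return m


# independent oracle: enumerate all permutations, residual partial formula
def brute_force_partial_mantel(M_v, M_b, C):
    iu = np.triu_indices(M_v.shape[0], k=1)
    b, c = M_b[iu], C[iu]

    def partial_r(perm):
        v = M_v[np.ix_(perm, perm)][iu]
        with np.errstate(all="ignore"):
            rvb = np.corrcoef(v, b)[0, 1]
            rvc = np.corrcoef(v, c)[0, 1]
            rbc = np.corrcoef(b, c)[0, 1]
            denom = (1 - rvc**2) * (1 - rbc**2)
            if denom <= 0:
                return np.nan
            return (rvb - rvc * rbc) / np.sqrt(denom)

    n = M_v.shape[0]
    r_obs = partial_r(np.arange(n))
    rs = [partial_r(np.array(p)) for p in itertools.permutations(range(n))]
    rs = [r for r in rs if not np.isnan(r)]  # undefined perms excluded
    p = np.mean([r >= r_obs - 1e-12 for r in rs])
    return r_obs, p


class TestPartialMantel:
    def test_identical_matrices_give_r_one(self):
        rng = np.random.default_rng(0)
        M = _sym(rng.random(15), 6)
        C = _sym((rng.random(15) < 0.5).astype(float), 6)
        r, p, used_partial = partial_mantel(M, M.copy(), C, seed=1)
        assert r == pytest.approx(1.0)
        assert not used_partial  # collinear pair falls back to simple Mantel

    def test_four_by_four_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            M_v = _sym((rng.random(6) < 0.5).astype(float), 4)
            M_b = _sym((rng.random(6) < 0.5).astype(float), 4)
            C = _sym((rng.random(6) < 0.5).astype(float), 4)
            try:
                r_exp, p_exp = brute_force_partial_mantel(M_v, M_b, C)
            except Exception:
                continue
            if not np.isfinite(r_exp) or abs(r_exp) >= 1 - 1e-9:
                continue
            try:
                r, p, _ = partial_mantel(M_v, M_b, C, method="exact", seed=0)
            except ValueError:
                continue
            assert r == pytest.approx(r_exp)
            assert p == pytest.approx(p_exp)

    def test_constant_matrix_rejected(self):
        M = np.zeros((5, 5))
        M2 = _sym(np.random.default_rng(1).random(10), 5)
        C = _sym([1, 0, 1, 0, 1, 0, 1, 0, 1, 0], 5)
        with pytest.raises(ValueError, match="constant"):
            partial_mantel(M, M2, C)

    def test_collinear_with_control_rejected(self):
        rng = np.random.default_rng(2)
        C = _sym((rng.random(10) < 0.5).astype(float), 5)
        M_b = _sym(rng.random(10), 5)
        with pytest.raises(ValueError, match="collinear with the control"):
            partial_mantel(C.copy(), M_b, C)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(4)
        M_v = _sym(rng.random(15), 6)
        M_b = _sym(rng.random(15), 6)
        C = _sym((rng.random(15) < 0.5).astype(float), 6)
        r1, _, _ = partial_mantel(M_v, M_b, C, seed=0, method="mc", n_perm=49)
        perm = rng.permutation(6)
        r2, _, _ = partial_mantel(
            M_v[np.ix_(perm, perm)], M_b[np.ix_(perm, perm)],
            C[np.ix_(perm, perm)], seed=0, method="mc", n_perm=49,
        )
        assert r1 == pytest.approx(r2)

    def test_simple_mantel_agrees_with_skbio(self):
        pytest.importorskip("skbio")
        from skbio.stats.distance import DistanceMatrix, mantel

        rng = np.random.default_rng(5)
        M_v = _sym(rng.random(21), 7)
        M_b = _sym(rng.random(21), 7)
        r, p, _ = partial_mantel(M_v, M_b, None, method="exact")
        r_sk, p_sk, _ = mantel(
            DistanceMatrix(M_v), DistanceMatrix(M_b),
            method="pearson", permutations=999, alternative="greater",
        )
        assert r == pytest.approx(float(r_sk))
        assert abs(p - float(p_sk)) < 0.08


class TestNonrandomLinkage:
    def test_hand_enumeration(self):
        # 10 pairs: virus shared in 6, bacterium in 5, both in 4
        sv = [0, 0, 0, 0, 0, 0, 1, 1, 1, 1]      # 0 = shared
        sb = [0, 0, 0, 0, 1, 1, 0, 1, 1, 1]
        M_v = _sym(sv, 5)
        M_b = _sym(sb, 5)
        with pytest.warns(UserWarning, match="expected cell count"):
            delta, p = nonrandom_linkage(M_v, M_b)
        assert delta == pytest.approx(0.4 - 0.3)
        # oracle: chi-squared by hand on table [[4,2],[1,3]]
        a, b, c, d = 4, 2, 1, 3
        n = a + b + c + d
        chi2 = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        from scipy.stats import chi2 as chi2_dist

        assert p == pytest.approx(chi2_dist.sf(chi2, 1))

    def test_identical_matrices_algebraic_identity(self):
        rng = np.random.default_rng(6)
        M = _sym((rng.random(45) < 0.4).astype(float), 10)
        delta, _ = nonrandom_linkage(M, M.copy())
        f = (M[np.triu_indices(10, 1)] == 0).mean()
        assert delta == pytest.approx(f - f * f)

    def test_null_mean_near_zero(self):
        rng = np.random.default_rng(7)
        deltas = []
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for _ in range(200):
                M_v = _sym((rng.random(45) < 0.5).astype(float), 10)
                M_b = _sym((rng.random(45) < 0.5).astype(float), 10)
                deltas.append(nonrandom_linkage(M_v, M_b)[0])
        se = np.std(deltas, ddof=1) / np.sqrt(len(deltas))
        assert abs(np.mean(deltas)) < 3 * se + 1e-12

    def test_degenerate_margin_p_one(self):
        M_v = np.zeros((4, 4))  # everything shared
        M_b = _sym([0, 1, 0, 1, 0, 1], 4)
        with pytest.warns(UserWarning, match="degenerate margin"):
            delta, p = nonrandom_linkage(M_v, M_b)
        assert p == 1.0

    def test_delta_bound_at_half_marginals(self):
        # with both marginal sharing fractions 0.5, |delta| <= 0.25
        rng = np.random.default_rng(8)
        for _ in range(50):
            vals_v = np.array([0.0] * 5 + [1.0] * 5)
            vals_b = vals_v.copy()
            rng.shuffle(vals_v)
            rng.shuffle(vals_b)
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                delta, _ = nonrandom_linkage(_sym(vals_v, 5), _sym(vals_b, 5))
            assert -0.25 - 1e-12 <= delta <= 0.25 + 1e-12


class TestConcurrentSubset:
    @staticmethod
    def _meta():
        rows = []
        for ind, fam, role in (("M1", "F1", "mother"), ("I1", "F1", "infant"),
                               ("M2", "F2", "mother"), ("I2", "F2", "infant")):
            for tp in ("M1", "M3"):
                for source in ("VLP", "MGS", "TOTAL"):
                    rows.append({
                        "sample_id": f"{ind}_{tp}_{source}",
                        "individual_id": ind, "family_id": fam, "role": role,
                        "timepoint_label": tp, "age_days": 30,
                        "source": source, "library_size": 10, "dna_conc": 1.0,
                    })
        return pd.DataFrame(rows)

    def test_small_intersection_skipped(self):
        meta = self._meta()
        v_samples = ["M1_M1_VLP", "I1_M1_VLP", "M2_M1_VLP"]
        b_samples = ["M1_M1_TOTAL", "I1_M1_TOTAL", "M2_M1_TOTAL"]
        ev = np.zeros((3, 3))
        assert build_concurrent_subset(
            ev, v_samples, ev, b_samples, meta
        ) is None  # 3 units < 4

    def test_vlp_priority_and_control_matrix(self):
        meta = self._meta()
        v_samples = ["M1_M1_VLP", "M1_M1_MGS", "I1_M1_VLP", "M2_M1_VLP",
                     "I2_M1_VLP", "M1_M3_MGS"]
        b_samples = ["M1_M1_TOTAL", "I1_M1_TOTAL", "M2_M1_TOTAL",
                     "I2_M1_TOTAL", "M1_M3_TOTAL"]
        ev_v = np.zeros((6, 6))
        ev_b = np.zeros((5, 5))
        sub = build_concurrent_subset(
            ev_v, v_samples, ev_b, b_samples, meta,
            virus_id="v", bacterium_id="b",
        )
        assert len(sub.units) == 5
        # the (M1, M1) unit uses the VLP record, not MGS
        i_m1 = sub.units.index(("M1", "M1"))
        assert v_samples[0] == "M1_M1_VLP"
        # mother and her infant are different individuals in the control
        i_i1 = sub.units.index(("I1", "M1"))
        assert sub.C[i_m1, i_i1] == 1.0
        # longitudinal samples of one individual are the same individual
        i_m1b = sub.units.index(("M1", "M3"))
        assert sub.C[i_m1, i_m1b] == 0.0

    def test_events_flip_to_zero_is_shared(self):
        meta = self._meta()
        v_samples = ["M1_M1_VLP", "I1_M1_VLP", "M2_M1_VLP", "I2_M1_VLP"]
        b_samples = ["M1_M1_TOTAL", "I1_M1_TOTAL", "M2_M1_TOTAL",
                     "I2_M1_TOTAL"]
        events = np.ones((4, 4))  # all sharing events
        sub = build_concurrent_subset(events, v_samples, events, b_samples,
                                      meta)
        assert sub.M_v.sum() == 0  # shared -> 0 in the linkage convention


class TestHostVsRandom:
    def test_hand_hypergeometric(self):
        from scipy.stats import hypergeom

        host = [True] * 14 + [False] * 18
        rand = [True] * 2 + [False] * 30
        p = host_vs_random_enrichment(host, rand)
        # one-sided Fisher == hypergeometric tail P(X >= 14)
        expected = hypergeom.sf(13, 64, 16, 32)
        assert p == pytest.approx(expected)

    def test_equal_frequencies_not_significant(self):
        assert host_vs_random_enrichment([True, False], [True, False]) >= 0.5

    def test_empty_class_warns_p_one(self):
        with pytest.warns(UserWarning, match="empty pair class"):
            assert host_vs_random_enrichment([], [True]) == 1.0
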