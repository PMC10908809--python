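"""Validation experiments on synthetic cohorts with planted ground truth.

These are the package's own calibration and recovery studies: type-I error
of the related/unrelated permutation test under a no-transmission null,
the null behaviour of the non-random-linkage statistic and the Mantel test,
and sensitivity / false-discovery of the full transmission pipeline on a
cohort with planted transmission and phage-host coupling.  They are used by
the test suite and by ``scripts/acceptance.py``.

A note on the type-I design: pairwise distances that share a sample are not
independent — a long branch on one mother's strain shifts every pair she
takes part in — so pooling all mother-infant pairs of a cohort makes the
label-permutation test *conservative* (the shared shifts cancel in the
ranks).  The calibration experiment therefore scores each entity on a focal
design in which every pair is an exchangeable unit: one infant sample
compared against a single sample from each mother (its own mother being the
one related pair).  The conservative direction of the pooled design is
checked separately.
"""

from __future__ import annotations

import warnings

import numpy as np

from .cotransmission import nonrandom_linkage, partial_mantel
from .distances import StrainAlignment, pairwise_k2p, trim_alignment
from .pipeline import RunConfig, run_pipeline
from .synthetic import CohortConfig, generate_cohort
from .transmission import label_pairs, related_unrelated_permutation_test

__all__ = [
    "permutation_typeI_experiment",
    "pooled_typeI_experiment",
    "linkage_null_experiment",
    "mantel_typeI_experiment",
    "parameter_recovery_experiment",
]


def _null_cohort(n_entities: int, n_families: int, seq_length: int, seed: int):
    cfg = CohortConfig(
        n_families=n_families,
        infants_per_family=1,
        mother_timepoints=("M1",),
        infant_timepoints=("M1",),
        n_votus=n_entities,
        n_background_votus=0,
        n_bacteria=1,
        transmission_rate=0.0,
        coupling_rate=0.0,
        seq_length=seq_length,
        dropout=0.0,
        seed=seed,
    )
    return generate_cohort(cfg)


def permutation_typeI_experiment(
    n_entities: int = 500,
    n_families: int = 20,
    seq_length: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
    n_iter: int = 1000,
) -> dict:
    """Type-I error of the permutation distance test under no transmission.

    Each entity is scored on a focal design: one infant's strain against one
    strain per mother (the infant's own mother forms the single related
    pair, the other mothers the unrelated pairs), so the pairs are
    exchangeable units and the p-value is exactly uniform on {1/m, ..., 1}.
    Returns the rejection fraction at ``alpha`` and the p-values.
    """
    bundle = _null_cohort(n_entities, n_families, seq_length, seed)
    meta = bundle.metadata
    vlp = meta[meta["source"] == "VLP"].set_index("sample_id")
    mothers = sorted(vlp.index[vlp["role"] == "mother"])
    infants = sorted(vlp.index[vlp["role"] == "infant"])
    ps = []
    votus = sorted(e for e in bundle.alignments if e.startswith("vOTU"))
    for k, votu in enumerate(votus):
        aln = bundle.alignments[votu]
        focal = infants[k % len(infants)]
        sub = StrainAlignment(
            votu, {s: aln.records[s] for s in mothers + [focal]}
        )
        dset = pairwise_k2p(trim_alignment(sub, 100))
        labels = label_pairs(dset.sample_ids, meta)
        rel = dset.D[labels.loc[labels["relation"] == "related", "i"],
                     labels.loc[labels["relation"] == "related", "j"]]
        unrel = dset.D[labels.loc[labels["relation"] == "unrelated", "i"],
                       labels.loc[labels["relation"] == "unrelated", "j"]]
        ps.append(related_unrelated_permutation_test(
            rel, unrel, n_iter=n_iter, seed=seed + 1000 + k
        ))
    ps = np.array(ps)
    return {
        "rejection_rate": float((ps <= alpha).mean()),
        "n_entities": len(ps),
        "p_values": ps,
    }


def pooled_typeI_experiment(
    n_entities: int = 200,
    n_families: int = 6,
    seq_length: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
    n_iter: int = 1000,
) -> dict:
    """Rejection rate of the pooled (all mother-infant pairs) test under the
    null.  Shared samples across pairs make this design conservative; the
    practically relevant property is that it never exceeds the nominal
    level."""
    cfg = CohortConfig(
        n_families=n_families,
        mother_timepoints=("P7", "B"),
        infant_timepoints=("M1", "M6"),
        n_votus=n_entities,
        n_background_votus=0,
        n_bacteria=1,
        transmission_rate=0.0,
        seq_length=seq_length,
        dropout=0.0,
        seed=seed,
    )
    bundle = generate_cohort(cfg)
    ps = []
    rng = np.random.default_rng(seed + 1)
    for votu in sorted(e for e in bundle.alignments if e.startswith("vOTU")):
        dset = pairwise_k2p(trim_alignment(bundle.alignments[votu], 100))
        labels = label_pairs(dset.sample_ids, bundle.metadata)
        rel = dset.D[labels.loc[labels["relation"] == "related", "i"],
                     labels.loc[labels["relation"] == "related", "j"]]
        unrel = dset.D[labels.loc[labels["relation"] == "unrelated", "i"],
                       labels.loc[labels["relation"] == "unrelated", "j"]]
        ps.append(related_unrelated_permutation_test(
            rel, unrel, n_iter=n_iter, seed=rng.spawn(1)[0], method="mc"
        ))
    ps = np.array(ps)
    return {"rejection_rate": float((ps <= alpha).mean()), "p_values": ps}


def _random_symmetric_binary(n: int, p_one: float, rng) -> np.ndarray:
    iu = np.triu_indices(n, k=1)
    m = np.zeros((n, n))
    vals = (rng.random(len(iu[0])) < p_one).astype(float)
    m[iu] = vals
    return m + m.T


def linkage_null_experiment(
    n_sim: int = 500, n_units: int = 10, p_share: float = 0.5, seed: int = 0
) -> dict:
    """Mean non-random linkage Δ over independently drawn sharing matrices.

    With the virus and bacterium sharing patterns drawn independently, Δ has
    expectation 0 (up to the finite-sample covariance of the upper-triangle
    fractions); returns the mean, its Monte-Carlo standard error and the
    per-simulation values.
    """
    rng = np.random.default_rng(seed)
    deltas = np.empty(n_sim)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for k in range(n_sim):
            M_v = _random_symmetric_binary(n_units, 1 - p_share, rng)
            M_b = _random_symmetric_binary(n_units, 1 - p_share, rng)
            deltas[k], _ = nonrandom_linkage(M_v, M_b)
    return {
        "mean_delta": float(deltas.mean()),
        "mc_se": float(deltas.std(ddof=1) / np.sqrt(n_sim)),
        "deltas": deltas,
    }


def mantel_typeI_experiment(
    n_sim: int = 200, n_units: int = 12, n_perm: int = 199, seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Rejection rate of the (partial) Mantel test on independent matrices."""
    rng = np.random.default_rng(seed)
    rejections = 0
    done = 0
    while done < n_sim:
        M_v = _random_symmetric_binary(n_units, 0.5, rng)
        M_b = _random_symmetric_binary(n_units, 0.5, rng)
        C = _random_symmetric_binary(n_units, 0.5, rng)
        try:
            _, p, _ = partial_mantel(M_v, M_b, C, n_perm=n_perm, seed=rng)
        except ValueError:
            continue
        rejections += p <= alpha
        done += 1
    return {"rejection_rate": rejections / n_sim, "n_sim": n_sim}


def parameter_recovery_experiment(
    seed: int = 0,
    n_votus: int = 40,
    n_bacteria: int = 8,
    n_families: int = 6,
    transmission_rate: float = 0.5,
    coupling_rate: float = 1.0,
    seq_length: int = 20_000,
    d_within: float = 0.002,
    d_transmit: float = 0.005,
    d_unrelated: float = 0.1,
    n_iter: int = 1000,
    n_perm: int = 999,
) -> dict:
    """Sensitivity / false-discovery of transmission calls, and the
    co-transmission detection rate, on a planted cohort.

    Runs the full pipeline (curation -> abundance -> distances ->
    transmission -> co-transmission) on a cohort whose truth table is known
    and scores the per-vOTU transmitted calls (BH q < 0.05) and the
    coupled phage-host pairs flagged as co-transmitted (Mantel q < 0.05 with
    positive non-random linkage).
    """
    cohort = CohortConfig(
        n_families=n_families,
        mother_timepoints=("P7", "B", "M1", "M3"),
        infant_timepoints=("M1", "M3", "M6", "M12"),
        n_votus=n_votus,
        n_bacteria=n_bacteria,
        transmission_rate=transmission_rate,
        coupling_rate=coupling_rate,
        seq_length=seq_length,
        d_within=d_within,
        d_transmit=d_transmit,
        d_unrelated=d_unrelated,
        dropout=0.1,
        seed=seed,
    )
    out = run_pipeline(RunConfig(
        synthetic=cohort, n_iter=n_iter, n_perm=n_perm, seed=seed + 1
    ))
    results = out["transmission"].set_index("entity_id")
    truth = out["truth"].set_index("entity_id")

    votus = [e for e in results.index if e.startswith("vOTU")]
    calls = results.loc[votus, "transmitted_call"].astype(bool)
    actual = truth.loc[votus, "transmitted"].astype(bool)
    tp = int((calls & actual).sum())
    fp = int((calls & ~actual).sum())
    fn = int((~calls & actual).sum())
    sensitivity = tp / max(tp + fn, 1)
    fdp = fp / max(tp + fp, 1)

    linkage = out["linkage"]
    coupled = set(truth.index[truth["coupled_host_id"].astype(str) != ""])
    host_rows = linkage[
        (linkage["pair_class"] == "host") & linkage["virus_id"].isin(coupled)
    ]
    detection = (
        float(host_rows["cotransmitted"].mean()) if len(host_rows) else float("nan")
    )
    return {
        "sensitivity": float(sensitivity),
        "fdp": float(fdp),
        "tp": tp, "fp": fp, "fn": fn,
        "n_votus_tested": len(votus),
        "cotransmission_detection_rate": detection,
        "n_coupled_pairs": int(len(host_rows)),
        "pipeline": out,
    }
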