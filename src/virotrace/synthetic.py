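"""Synthetic mother-infant cohort generator with planted ground truth.

Emulates the sampling design of a longitudinal mother-infant gut virome
study: families of one mother and one or two infants, maternal samples from
pregnancy (months 3 and 7), birth and months 1-3 postpartum, infant samples
across the first year, VLP (virus-like particle) metaviromes alongside total
metagenomes, per-vOTU and per-bacterium consensus strain alignments, an
abundance table, scaffold annotation features and a virus->host map.

Strain sequences evolve on a star-like family tree under the K80
(Kimura two-parameter) substitution model:

* one root sequence per entity;
* one ancestor per family at expected distance ``d_unrelated/2`` from the
  root, so strains of different families sit ``~d_unrelated`` apart;
* each individual's base strain hangs ``d_transmit/2`` below the family
  ancestor when the strain was transmitted to (or carried by) that
  individual, and below a private ancestor otherwise — related mother-infant
  strains then sit ``~d_transmit`` apart while non-transmitted comparisons
  stay at ``~d_unrelated``;
* every longitudinal sample drifts ``d_within/2`` from the individual's base
  strain, so two samples of one individual differ by ``~d_within``.

Because K2P distances are additive in expectation along the branches, the
re-estimated pairwise distances are unbiased for these targets.

Transmission is planted per entity: a transmitted vOTU carries related
strains in every family, which gives every entity a clean transmitted /
not-transmitted truth label that downstream sensitivity and false-discovery
checks score against.  When a transmitted phage is *coupled* to its predicted
host (probability ``coupling_rate``), the host bacterium is forced to be
transmitted as well and its strain is reconstructed in exactly the timepoints
where the phage strain is, planting the phage-host co-transmission signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .distances import StrainAlignment

__all__ = ["CohortConfig", "CohortBundle", "evolve_sequence", "generate_cohort"]

# transition partner via XOR 2 (A<->G, C<->T); transversion targets per base
_TV = np.array([[1, 3], [0, 2], [1, 3], [0, 2]], dtype=np.uint8)
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: timepoint label -> age in days relative to birth (negative = pregnancy)
TIMEPOINT_DAYS = {
    "P3": -196, "P7": -84, "B": 0,
    "M1": 30, "M2": 61, "M3": 91, "M6": 182, "M9": 274, "M12": 365,
}

#: pre-/post-birth classification of maternal samples
PRE_BIRTH = {"P3", "P7", "B"}

# VLP metaviromes are not available at every timepoint in the emulated
# design (no week-12 maternal VLP, no month-9 infant VLP); total metagenomes
# cover all timepoints.
_MOTHER_VLP = {"P7", "B", "M1", "M2", "M3"}
_INFANT_VLP = {"M1", "M2", "M3", "M6", "M12"}


@dataclass
class CohortConfig:
    """Study-design and signal parameters for a synthetic cohort.

    Distances are expected K2P distances (substitutions/site) and must obey
    ``d_within <= d_transmit < d_unrelated`` for the planted truth to be
    recoverable.  ``kappa`` is the transition/transversion *rate* ratio of
    the K80 model (kappa=1 gives a 1:2 transition:transversion substitution
    ratio because there are two transversion channels per base).
    """

    n_families: int = 6
    infants_per_family: int = 1
    mother_timepoints: tuple[str, ...] = ("P3", "P7", "B", "M1", "M2", "M3")
    infant_timepoints: tuple[str, ...] = ("M1", "M2", "M3", "M6", "M9", "M12")
    n_votus: int = 20
    n_background_votus: int = 20
    n_bacteria: int = 10
    transmission_rate: float = 0.5
    coupling_rate: float = 0.5
    seq_length: int = 10_000
    d_within: float = 0.002
    d_transmit: float = 0.005
    d_unrelated: float = 0.1
    kappa: float = 2.0
    dropout: float = 0.1
    temperate_fraction: float = 0.45
    seed: int = 0

    def validate(self) -> None:
        if self.n_families < 1 or self.infants_per_family not in (1, 2):
            raise ValueError("need >=1 families with 1-2 infants each")
        if not self.mother_timepoints or not self.infant_timepoints:
            raise ValueError("mother and infant timepoint lists must be non-empty")
        unknown = (set(self.mother_timepoints) | set(self.infant_timepoints)) - set(
            TIMEPOINT_DAYS
        )
        if unknown:
            raise ValueError(f"unknown timepoint labels: {sorted(unknown)}")
        if self.seq_length < 1000:
            raise ValueError("seq_length must be >= 1000")
        if self.n_votus < 1 or self.n_bacteria < 1:
            raise ValueError("need >=1 vOTU and >=1 bacterium")
        if self.n_background_votus < 0:
            raise ValueError("n_background_votus must be >= 0")
        for name in ("transmission_rate", "coupling_rate", "dropout",
                     "temperate_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0 <= self.d_within <= self.d_transmit < self.d_unrelated:
            raise ValueError(
                "distances must satisfy 0 <= d_within <= d_transmit < d_unrelated"
            )
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")


@dataclass
class CohortBundle:
    """Everything the pipeline consumes, plus the planted truth."""

    config: CohortConfig
    metadata: pd.DataFrame          # SampleRecord table
    coverage: pd.DataFrame          # CoverageRecord table (VLP samples)
    library_sizes: pd.Series        # per-sample mapped-read totals
    annotations: pd.DataFrame       # ScaffoldAnnotation features per vOTU
    alignments: dict[str, StrainAlignment]   # entity_id -> strain alignment
    host_map: pd.DataFrame          # virus_id, host_id, confidence
    truth: pd.DataFrame             # entity_id, transmitted, coupled_host_id
    lifestyle: pd.Series = field(default=None)  # vOTU -> temperate|virulent


def _k80_site_probs(d: float, kappa: float) -> tuple[float, float]:
    """Expected transition (P) and transversion (Q) proportions after
    evolving for expected distance ``d`` under K80 with ratio ``kappa``.

    With per-channel rates alpha (transition) and beta (each of two
    transversions), d = (alpha + 2 beta) t and
        P(t) = 1/4 - 1/2 exp(-2(alpha+beta)t) + 1/4 exp(-4 beta t)
        Q(t) = 1/2 - 1/2 exp(-4 beta t)
    which the K2P estimator inverts exactly: the expected estimate equals d.
    """
    bt = d / (kappa + 2.0)
    at = kappa * bt
    e1 = np.exp(-2.0 * (at + bt))
    e2 = np.exp(-4.0 * bt)
    P = 0.25 - 0.5 * e1 + 0.25 * e2
    Q = 0.5 - 0.5 * e2
    return float(P), float(Q)


_SATURATION_D = 15.0  # beyond this the expected P,Q are numerically at the
# K80 fixed point (P=1/4, Q=1/2) and the distance is unrecoverable


def evolve_sequence(
    ancestor: str,
    d_target: float,
    kappa: float = 2.0,
    seed: int | np.random.Generator = 0,
) -> str:
    """Evolve a copy of ``ancestor`` to expected K2P distance ``d_target``.

    Sites mutate independently with the analytic K80 transition
    probabilities, so the expected re-estimated K2P distance between ancestor
    and child equals ``d_target`` exactly (no per-site Bernoulli
    approximation).  Deterministic given the seed.
    """
    if d_target < 0 or not np.isfinite(d_target):
        raise ValueError(f"d_target must be finite and >= 0, got {d_target}")
    if kappa <= 0:
        raise ValueError("kappa must be > 0")
    if d_target >= _SATURATION_D:
        raise ValueError(
            f"d_target={d_target} is beyond K80 saturation; the pairwise "
            "estimator cannot recover distances this large"
        )
    idx = np.frombuffer(ancestor.encode("ascii"), dtype=np.uint8)
    codes = np.full(256, 255, dtype=np.uint8)
    codes[_BASES] = np.arange(4, dtype=np.uint8)
    x = codes[idx]
    if (x == 255).any():
        raise ValueError("ancestor must be over {A,C,G,T}")
    if d_target == 0:
        return ancestor
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    P, Q = _k80_site_probs(d_target, kappa)
    u = rng.random(x.size)
    child = x.copy()
    is_ts = u < P
    child[is_ts] = x[is_ts] ^ 2
    is_tv = (u >= P) & (u < P + Q)
    which = (u[is_tv] - P) * 2.0 / Q >= 1.0
    child[is_tv] = _TV[x[is_tv], which.astype(np.intp)]
    return _BASES[child].tobytes().decode("ascii")


def _random_sequence(length: int, rng: np.random.Generator) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def generate_cohort(config: CohortConfig) -> CohortBundle:
    """Generate a complete, deterministic synthetic cohort bundle."""
    config.validate()
    cfg = config
    root_rng = np.random.default_rng(cfg.seed)
    # independent child generators per concern, fanned out via spawning so
    # that e.g. enlarging n_votus does not reshuffle the metadata draws
    (meta_rng, truth_rng, seq_rng, abund_rng, ann_rng) = root_rng.spawn(5)

    # ---- sample metadata -------------------------------------------------
    rows = []
    for f in range(cfg.n_families):
        fam = f"FAM{f:03d}"
        members = [(f"{fam}_M", "mother", cfg.mother_timepoints)]
        for i in range(cfg.infants_per_family):
            suffix = "I" if cfg.infants_per_family == 1 else f"I{i + 1}"
            members.append((f"{fam}_{suffix}", "infant", cfg.infant_timepoints))
        for ind, role, tps in members:
            vlp_ok = _MOTHER_VLP if role == "mother" else _INFANT_VLP
            for tp in tps:
                if meta_rng.random() < cfg.dropout:
                    continue
                for source in ("VLP", "TOTAL"):
                    if source == "VLP" and tp not in vlp_ok:
                        continue
                    rows.append({
                        "sample_id": f"{ind}_{tp}_{source}",
                        "individual_id": ind,
                        "family_id": fam,
                        "role": role,
                        "timepoint_label": tp,
                        "age_days": TIMEPOINT_DAYS[tp],
                        "source": source,
                        "library_size": int(meta_rng.integers(5_000_000, 40_000_000)),
                        "dna_conc": round(float(meta_rng.lognormal(1.0, 0.8)), 3),
                    })
    metadata = pd.DataFrame(rows)
    if metadata.empty:
        raise ValueError("cohort design produced no samples (dropout too high?)")
    # guarantee at least one retained timepoint per individual so planted
    # transmitted strains are always observable
    all_inds = {
        f"FAM{f:03d}_M" for f in range(cfg.n_families)
    } | {
        f"FAM{f:03d}_{'I' if cfg.infants_per_family == 1 else 'I' + str(i + 1)}"
        for f in range(cfg.n_families) for i in range(cfg.infants_per_family)
    }
    missing = sorted(all_inds - set(metadata["individual_id"]))
    extra = []
    for ind in missing:
        role = "mother" if ind.endswith("_M") else "infant"
        tps = cfg.mother_timepoints if role == "mother" else cfg.infant_timepoints
        vlp_ok = _MOTHER_VLP if role == "mother" else _INFANT_VLP
        tp = next((t for t in tps if t in vlp_ok), tps[0])
        for source in ("VLP", "TOTAL"):
            if source == "VLP" and tp not in vlp_ok:
                continue
            extra.append({
                "sample_id": f"{ind}_{tp}_{source}",
                "individual_id": ind,
                "family_id": ind.split("_")[0],
                "role": role,
                "timepoint_label": tp,
                "age_days": TIMEPOINT_DAYS[tp],
                "source": source,
                "library_size": int(meta_rng.integers(5_000_000, 40_000_000)),
                "dna_conc": round(float(meta_rng.lognormal(1.0, 0.8)), 3),
            })
    if extra:
        metadata = pd.concat([metadata, pd.DataFrame(extra)], ignore_index=True)

    votus = [f"vOTU{v:04d}" for v in range(cfg.n_votus)]
    bacteria = [f"BACT{b:04d}" for b in range(cfg.n_bacteria)]

    # ---- planted truth ---------------------------------------------------
    host_of = {v: bacteria[i % cfg.n_bacteria] for i, v in enumerate(votus)}
    v_transmitted = truth_rng.random(cfg.n_votus) < cfg.transmission_rate
    coupled = v_transmitted & (truth_rng.random(cfg.n_votus) < cfg.coupling_rate)
    b_transmitted = {b: bool(truth_rng.random() < cfg.transmission_rate)
                     for b in bacteria}
    for v, c in zip(votus, coupled):
        if c:
            b_transmitted[host_of[v]] = True
    temperate = truth_rng.random(cfg.n_votus) < cfg.temperate_fraction

    truth_rows = []
    for i, v in enumerate(votus):
        truth_rows.append({
            "entity_id": v,
            "kind": "virus",
            "transmitted": bool(v_transmitted[i]),
            "coupled_host_id": host_of[v] if coupled[i] else "",
        })
    for b in bacteria:
        truth_rows.append({
            "entity_id": b, "kind": "bacterium",
            "transmitted": b_transmitted[b], "coupled_host_id": "",
        })
    truth = pd.DataFrame(truth_rows)

    host_map = pd.DataFrame({
        "virus_id": votus,
        "host_id": [host_of[v] for v in votus],
        "confidence": np.round(truth_rng.uniform(0.8, 1.0, cfg.n_votus), 3),
    })

    # ---- strain alignments ----------------------------------------------
    meta_by_ind = metadata.groupby("individual_id")
    coupled_host_samples: dict[tuple[str, str], list[str]] = {}
    alignments: dict[str, StrainAlignment] = {}

    def entity_alignment(entity: str, transmitted: bool, source: str,
                         rng: np.random.Generator,
                         forced_tps: dict[str, list[str]] | None = None,
                         ) -> tuple[StrainAlignment, dict[str, list[str]]]:
        root = _random_sequence(cfg.seq_length, rng)
        records: dict[str, str] = {}
        used_tps: dict[str, list[str]] = {}
        for f in range(cfg.n_families):
            fam = f"FAM{f:03d}"
            fam_anc = evolve_sequence(root, cfg.d_unrelated / 2, cfg.kappa, rng)
            fam_inds = [i for i in sorted(all_inds) if i.startswith(fam)]
            for ind in fam_inds:
                if ind not in meta_by_ind.groups:
                    continue
                sub = meta_by_ind.get_group(ind)
                sub = sub[sub["source"] == source]
                if forced_tps is not None:
                    tps = forced_tps.get(ind, [])
                    sub = sub[sub["timepoint_label"].isin(tps)]
                if sub.empty:
                    continue
                is_infant = not ind.endswith("_M")
                if transmitted or not is_infant:
                    base_anc = fam_anc
                else:
                    # non-transmitted infant strain: private lineage at the
                    # same depth, so related and unrelated pair distances
                    # share one expectation under the no-transmission null
                    base_anc = evolve_sequence(
                        root, cfg.d_unrelated / 2, cfg.kappa, rng
                    )
                base = evolve_sequence(base_anc, cfg.d_transmit / 2, cfg.kappa, rng)
                used_tps[ind] = sorted(sub["timepoint_label"].unique())
                for _, row in sub.iterrows():
                    records[row["sample_id"]] = evolve_sequence(
                        base, cfg.d_within / 2, cfg.kappa, rng
                    )
        return StrainAlignment(entity, records), used_tps

    for i, v in enumerate(votus):
        aln, used = entity_alignment(v, bool(v_transmitted[i]), "VLP", seq_rng)
        alignments[v] = aln
        if coupled[i]:
            coupled_host_samples[(host_of[v], v)] = used

    forced_for_host: dict[str, dict[str, list[str]]] = {}
    for (b, _v), used in coupled_host_samples.items():
        merged = forced_for_host.setdefault(b, {})
        for ind, tps in used.items():
            merged[ind] = sorted(set(merged.get(ind, [])) | set(tps))
    for b in bacteria:
        aln, _ = entity_alignment(
            b, b_transmitted[b], "TOTAL", seq_rng,
            forced_tps=forced_for_host.get(b),
        )
        alignments[b] = aln

    # ---- abundance / coverage -------------------------------------------
    vlp = metadata[metadata["source"] == "VLP"]
    lengths = ann_rng.integers(3_500, 80_000, size=cfg.n_votus)
    base_log = abund_rng.normal(1.0, 1.0, size=cfg.n_votus)
    # compositional mother/infant separation: per-vOTU role offset, with
    # temperate phages skewed towards infants (their early viromes are
    # dominated by induced prophages)
    infant_shift = abund_rng.normal(0.0, 1.0, size=cfg.n_votus)
    infant_shift[temperate] += 1.0
    cov_rows = []
    for _, samp in vlp.iterrows():
        is_infant = samp["role"] == "infant"
        logs = base_log + (infant_shift if is_infant else 0.0)
        logs = logs + abund_rng.normal(0.0, 0.5, size=cfg.n_votus)
        present = abund_rng.random(cfg.n_votus) < (0.85 if not is_infant else 0.6)
        for j, v in enumerate(votus):
            if not present[j]:
                continue
            rpk_signal = 10.0 ** logs[j]
            count = int(rpk_signal * (lengths[j] / 1000.0)
                        * (samp["library_size"] / 1e6) / 100.0)
            if count <= 0:
                continue
            breadth = float(np.clip(abund_rng.beta(12, 1), 0.0, 1.0))
            cov_rows.append({
                "scaffold_id": v,
                "sample_id": samp["sample_id"],
                "read_count": count,
                "breadth": round(breadth, 4),
                "scaffold_length": int(lengths[j]),
            })
    # a consensus strain is only reconstructed where the genome is covered
    # at >95% breadth, so samples backing an alignment record must carry a
    # matching coverage record
    by_key = {(r["scaffold_id"], r["sample_id"]): r for r in cov_rows}
    for v in votus:
        for sid in alignments[v].sample_ids:
            row = by_key.get((v, sid))
            if row is None:
                cov_rows.append({
                    "scaffold_id": v, "sample_id": sid,
                    "read_count": int(50 * lengths[votus.index(v)] / 1000),
                    "breadth": 0.99,
                    "scaffold_length": int(lengths[votus.index(v)]),
                })
            elif row["breadth"] <= 0.95:
                row["breadth"] = round(0.96 + 0.04 * abund_rng.random(), 4)
    # background vOTUs: abundance-only community members (no strain
    # alignments), the bulk of a real virome profile — they give the
    # community metrics realistic presence/absence turnover and give the
    # curation stage genuine contaminants to remove
    background = [f"bgOTU{k:04d}" for k in range(cfg.n_background_votus)]
    bg_lengths = ann_rng.integers(1_500, 60_000, size=cfg.n_background_votus)
    bg_temperate = truth_rng.random(cfg.n_background_votus) < cfg.temperate_fraction
    bg_base = abund_rng.normal(0.5, 1.0, size=cfg.n_background_votus)
    bg_shift = abund_rng.normal(0.0, 1.0, size=cfg.n_background_votus)
    bg_shift[bg_temperate] += 1.0
    # per-individual carriage makes presence persistent within a person
    carriage: dict[tuple[str, str], bool] = {}
    for _, samp in vlp.iterrows():
        is_infant = samp["role"] == "infant"
        logs = bg_base + (bg_shift if is_infant else 0.0)
        logs = logs + abund_rng.normal(0.0, 0.5, size=cfg.n_background_votus)
        for j, v in enumerate(background):
            key = (v, samp["individual_id"])
            if key not in carriage:
                carriage[key] = bool(
                    abund_rng.random() < (0.45 if is_infant else 0.75)
                )
            present = carriage[key] and abund_rng.random() < 0.8
            if not present:
                continue
            count = int(10.0 ** logs[j] * (bg_lengths[j] / 1000.0)
                        * (samp["library_size"] / 1e6) / 100.0)
            if count <= 0:
                continue
            cov_rows.append({
                "scaffold_id": v,
                "sample_id": samp["sample_id"],
                "read_count": count,
                "breadth": round(float(np.clip(abund_rng.beta(8, 1), 0, 1)), 4),
                "scaffold_length": int(bg_lengths[j]),
            })
    coverage = pd.DataFrame(cov_rows)
    library_sizes = metadata.set_index("sample_id")["library_size"].astype(float)

    # ---- scaffold annotations -------------------------------------------
    ann_rows = []
    for j, v in enumerate(votus):
        temp = bool(temperate[j])
        circ = bool(ann_rng.random() < 0.5)
        pvogs = int(ann_rng.integers(3, 12))
        ann_rows.append({
            "scaffold_id": v,
            "length_bp": int(lengths[j]),
            "circular": circ,
            "virsorter_positive": bool(ann_rng.random() < 0.7) or not circ,
            "pvog_hits": pvogs,
            "pvog_per_10kb": round(pvogs / (lengths[j] / 1e4), 3),
            "ribosomal_protein_genes": 0,
            "rrna_hit": False,
            "refseq_viral_hit": bool(ann_rng.random() < 0.3),
            "crass_hit": bool(ann_rng.random() < 0.05),
            "nt_hit": False,
            "vc_id": f"VC{j // 3:03d}",
            "negctrl_cluster": False,
            "checkv_quality": "High-quality" if ann_rng.random() < 0.7 else "Complete",
            "integrase": temp and bool(ann_rng.random() < 0.7),
            "recombinase": temp,
            "ci_repressor": temp,
        })
        if ann_rows[-1]["integrase"] is False and temp:
            # temperate via recombinase + CI repressor co-presence
            ann_rows[-1]["recombinase"] = True
            ann_rows[-1]["ci_repressor"] = True
    for j, v in enumerate(background):
        temp = bool(bg_temperate[j])
        u = ann_rng.random()
        contaminated = u < 0.15          # negative-control cluster member
        cellular = 0.15 <= u < 0.25      # rRNA-carrying, condemned with its VC
        pvogs = int(ann_rng.integers(0, 8))
        ann_rows.append({
            "scaffold_id": v,
            "length_bp": int(bg_lengths[j]),
            "circular": bool(ann_rng.random() < 0.3),
            "virsorter_positive": bool(ann_rng.random() < 0.6) and not cellular,
            "pvog_hits": pvogs,
            "pvog_per_10kb": round(pvogs / (bg_lengths[j] / 1e4), 3),
            "ribosomal_protein_genes": 1 if cellular else 0,
            "rrna_hit": cellular,
            "refseq_viral_hit": bool(ann_rng.random() < 0.2),
            "crass_hit": False,
            "nt_hit": bool(ann_rng.random() < 0.3),
            "vc_id": f"BGVC{j:03d}",
            "negctrl_cluster": contaminated,
            "checkv_quality": "Medium-quality",
            "integrase": temp,
            "recombinase": False,
            "ci_repressor": False,
        })
    annotations = pd.DataFrame(ann_rows)
    lifestyle = pd.Series(
        np.concatenate([
            np.where(temperate, "temperate", "virulent"),
            np.where(bg_temperate, "temperate", "virulent"),
        ]),
        index=votus + background,
        name="lifestyle",
    )

    return CohortBundle(
        config=cfg,
        metadata=metadata.reset_index(drop=True),
        coverage=coverage.reset_index(drop=True),
        library_sizes=library_sizes,
        annotations=annotations,
        alignments=alignments,
        host_map=host_map,
        truth=truth,
        lifestyle=lifestyle,
    )


def config_to_dict(config: CohortConfig) -> dict:
    d = asdict(config)
    d["mother_timepoints"] = list(config.mother_timepoints)
    d["infant_timepoints"] = list(config.infant_timepoints)
    return d
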