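"""End-to-end orchestration: curation -> abundance -> dynamics -> distances
-> transmission -> co-transmission, with a machine-readable run report.

Every stage is a pure function of its inputs and the configuration; the run
report accounts for every record dropped by a filter, and identical
config+seed yields identical outputs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import curation, dynamics, io, profiles
from .cotransmission import analyze_pair, build_concurrent_subset
from .distances import pairwise_k2p, trim_alignment
from .synthetic import CohortConfig, generate_cohort, config_to_dict
from .transmission import analyze_transmission, bh_adjust

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Thresholds and inputs for one pipeline run.

    Defaults are the study conventions: breadth gate 0.75, strain-presence
    breadth 0.95, persistent-virome presence fraction 0.75, candidate length
    3 kbp with >=5 sharing families, 100 bp alignment end-trim, 1000
    label permutations for the distance test, 999 Mantel permutations,
    alpha = 0.05.
    """

    input_dir: str | None = None
    synthetic: CohortConfig | None = None
    output_dir: str | None = None
    breadth_threshold: float = 0.75
    presence_breadth: float = 0.95
    ppv_threshold: float = 0.75
    ppv_min_samples: int = 3
    candidate_min_length: int = 3000
    candidate_min_families: int = 5
    trim_bp: int = 100
    n_iter: int = 1000
    n_perm: int = 999
    alpha: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if (self.input_dir is None) == (self.synthetic is None):
            raise ValueError("provide exactly one of input_dir or synthetic")
        for name, lo, hi in (
            ("breadth_threshold", 0.0, 1.0),
            ("presence_breadth", 0.0, 1.0),
            ("ppv_threshold", 0.0, 1.0),
            ("alpha", 0.0, 1.0),
        ):
            v = getattr(self, name)
            if not lo < v <= hi:
                raise ValueError(f"{name} must lie in ({lo}, {hi}], got {v}")
        for name in ("candidate_min_length", "candidate_min_families",
                     "n_iter", "n_perm", "ppv_min_samples"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.trim_bp < 0:
            raise ValueError("trim_bp must be >= 0")
        if self.synthetic is not None:
            self.synthetic.validate()

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.synthetic is not None:
            d["synthetic"] = config_to_dict(self.synthetic)
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "synthetic" in raw and raw["synthetic"] is not None:
            syn = dict(raw["synthetic"])
            for key in ("mother_timepoints", "infant_timepoints"):
                if key in syn:
                    syn[key] = tuple(syn[key])
            raw["synthetic"] = CohortConfig(**syn)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg


@dataclass
class RunReport:
    counts: dict = field(default_factory=dict)
    skipped: list = field(default_factory=list)
    results: dict = field(default_factory=dict)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns a dict of result tables and the report.

    When ``config.output_dir`` is set, per-stage TSVs, the serialized
    configuration and a JSON run report are written there.
    """
    config.validate()
    report = RunReport()

    # ---- inputs ----------------------------------------------------------
    if config.synthetic is not None:
        bundle = generate_cohort(config.synthetic)
        metadata = bundle.metadata
        coverage = bundle.coverage
        annotations = bundle.annotations
        host_map = bundle.host_map
        alignments = bundle.alignments
        truth = bundle.truth
    else:
        inputs = io.read_bundle_inputs(config.input_dir)
        metadata = inputs["metadata"]
        coverage = inputs["coverage"]
        annotations = inputs["annotations"]
        host_map = inputs["host_map"]
        alignments = inputs["alignments"]
        truth = inputs.get("truth")

    # ---- curation --------------------------------------------------------
    curated = curation.curate(annotations)
    report.counts["scaffolds_in"] = int(len(annotations))
    report.counts["scaffolds_retained"] = int(len(curated))
    report.counts["scaffolds_dropped"] = int(len(annotations) - len(curated))
    lifestyle = curated.set_index("scaffold_id")["lifestyle"]

    # ---- abundance -------------------------------------------------------
    retained_cov = coverage[coverage["scaffold_id"].isin(curated["scaffold_id"])]
    filtered = profiles.apply_breadth_filter(retained_cov, config.breadth_threshold)
    report.counts["coverage_records"] = int(len(retained_cov))
    report.counts["coverage_zeroed"] = int(
        (filtered["read_count"] == 0).sum() - (retained_cov["read_count"] == 0).sum()
    )
    library_sizes = metadata.set_index("sample_id")["library_size"].astype(float)
    matrix = profiles.rpkm_transform(filtered, library_sizes)
    by_host = profiles.aggregate_by_host(matrix, host_map)

    # ---- dynamics --------------------------------------------------------
    meta_idx = metadata.set_index("sample_id")
    vlp_cols = [c for c in matrix.columns if meta_idx.loc[c, "source"] == "VLP"]
    vmat = matrix[vlp_cols]
    nonzero = vmat.columns[vmat.sum(axis=0) > 0]
    vmat = vmat[nonzero]
    alpha_div = pd.Series(
        {c: dynamics.shannon(vmat[c]) for c in vmat.columns}, name="shannon"
    )
    temp_frac = dynamics.temperate_fraction(
        vmat, lifestyle.reindex(vmat.index).fillna("virulent")
    )
    partitions = []
    for ind, sub in meta_idx[meta_idx["source"] == "VLP"].groupby("individual_id"):
        cols = [c for c in sub.index if c in vmat.columns]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            part = dynamics.persistence_partition(
                vmat[cols], subject_id=ind,
                threshold=config.ppv_threshold,
                min_samples=config.ppv_min_samples,
            )
        if part is None:
            report.skipped.append(
                {"stage": "dynamics", "entity": ind, "reason": "too few samples"}
            )
            continue
        partitions.append({
            "subject_id": ind,
            "n_ppv": len(part.ppv_ids),
            "n_tdv": len(part.tdv_ids),
        })
    partitions = pd.DataFrame(partitions)

    # ---- strain candidates & distances ------------------------------------
    breadth_matrix = profiles.coverage_to_matrix(retained_cov, value="breadth")
    candidates = curation.select_strain_candidates(
        breadth_matrix, curated, metadata,
        min_breadth=config.presence_breadth,
        min_length=config.candidate_min_length,
        min_families=config.candidate_min_families,
    )
    report.counts["strain_candidates"] = len(candidates)
    dist_sets = {}
    virus_ids = set(host_map["virus_id"])
    for entity_id, aln in sorted(alignments.items()):
        if entity_id in virus_ids and entity_id not in candidates:
            report.skipped.append({
                "stage": "distances", "entity": entity_id,
                "reason": "not a strain candidate",
            })
            continue
        try:
            trimmed = trim_alignment(aln, config.trim_bp)
        except ValueError as err:
            report.skipped.append({
                "stage": "distances", "entity": entity_id, "reason": str(err)
            })
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dist_sets[entity_id] = pairwise_k2p(trimmed)

    # ---- transmission -----------------------------------------------------
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        results, events = analyze_transmission(
            dist_sets, metadata,
            n_iter=config.n_iter, seed=config.seed, alpha=config.alpha,
        )

    # ---- co-transmission --------------------------------------------------
    rng = np.random.default_rng(config.seed + 1)
    linkage_rows = []
    host_of = dict(zip(host_map["virus_id"], host_map["host_id"]))
    analyzed_viruses = [
        e for e in results["entity_id"] if e in host_of
    ] if not results.empty else []
    bacteria_ids = sorted(
        {e for e in events if e not in virus_ids}
    )
    for v in analyzed_viruses:
        partners = [("host", host_of[v])]
        others = [b for b in bacteria_ids if b != host_of[v]]
        if others:
            partners.append(("random", others[rng.integers(len(others))]))
        for pair_class, b in partners:
            if b not in events:
                continue
            subset = build_concurrent_subset(
                events[v], dist_sets[v].sample_ids,
                events[b], dist_sets[b].sample_ids,
                metadata, virus_id=v, bacterium_id=b,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = analyze_pair(
                    subset, n_perm=config.n_perm, seed=rng.spawn(1)[0],
                    virus_id=v, bacterium_id=b,
                )
            row = asdict(res)
            row["pair_class"] = pair_class
            linkage_rows.append(row)
    linkage = pd.DataFrame(linkage_rows)
    if not linkage.empty:
        ok = linkage["status"] == "ok"
        linkage["q_mantel"] = np.nan
        if ok.any():
            linkage.loc[ok, "q_mantel"] = bh_adjust(linkage.loc[ok, "p_mantel"])
        linkage["cotransmitted"] = (
            (linkage["q_mantel"] < config.alpha)
            & (linkage["nonrandom_linkage"] > 0)
        ).fillna(False)

    # ---- truth comparison -------------------------------------------------
    confusion = None
    if truth is not None and not results.empty:
        t = truth.set_index("entity_id")["transmitted"]
        joined = results.set_index("entity_id")
        shared = joined.index.intersection(t.index)
        calls = joined.loc[shared, "transmitted_call"].astype(bool)
        actual = t.loc[shared].astype(bool)
        confusion = {
            "tp": int((calls & actual).sum()),
            "fp": int((calls & ~actual).sum()),
            "fn": int((~calls & actual).sum()),
            "tn": int((~calls & ~actual).sum()),
        }
        report.results["confusion"] = confusion

    out = {
        "metadata": metadata,
        "abundance": matrix,
        "abundance_by_host": by_host,
        "alpha_diversity": alpha_div,
        "temperate_fraction": temp_frac,
        "persistence": partitions,
        "curated": curated,
        "candidates": candidates,
        "distances": dist_sets,
        "transmission": results,
        "sharing_events": events,
        "linkage": linkage,
        "truth": truth,
        "confusion": confusion,
        "report": report,
    }

    # ---- outputs ----------------------------------------------------------
    if config.output_dir is not None:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "config.yaml", "w") as fh:
            yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
        io.write_metadata(metadata, outdir / "metadata.tsv")
        io.write_abundance(matrix, outdir / "abundance_rpkm.tsv")
        io.write_abundance(by_host, outdir / "abundance_by_host.tsv")
        curated.to_csv(outdir / "curated_scaffolds.tsv", sep="\t", index=False)
        alpha_div.rename_axis("sample_id").to_csv(
            outdir / "alpha_diversity.tsv", sep="\t"
        )
        temp_frac.rename("temperate_fraction").rename_axis("sample_id").to_csv(
            outdir / "temperate_fraction.tsv", sep="\t"
        )
        if not partitions.empty:
            partitions.to_csv(outdir / "persistence.tsv", sep="\t", index=False)
        if not results.empty:
            results.to_csv(outdir / "transmission.tsv", sep="\t", index=False)
        if not linkage.empty:
            linkage.to_csv(outdir / "cotransmission.tsv", sep="\t", index=False)
        with open(outdir / "report.json", "w") as fh:
            json.dump(
                {
                    "counts": report.counts,
                    "skipped": report.skipped,
                    "results": report.results,
                },
                fh, indent=2, sort_keys=True,
            )
    return out
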