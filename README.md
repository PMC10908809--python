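# virotrace

Strain-resolved analysis of mother-to-infant gut virome transmission.

Longitudinal mother–infant cohorts ask whether infants acquire gut viruses
(mostly bacteriophages) from their mothers, and whether phages travel
together with their bacterial hosts. Answering this requires more than
presence/absence overlap: two people can carry the same viral species (vOTU)
without any transmission having occurred. `virotrace` implements the
strain-level computation behind such studies, for researchers who have
already run the usual assembly/annotation stack (read mapping, VirSorter,
CheckV, vConTACT2, iPHoP, StrainPhlAn-style consensus calling) and need the
downstream inference:

* **Scaffold curation** — a rule engine for viral inclusion (six evidence
  criteria), negative-control dereplication, genus-cluster decontamination
  with member rescue, and temperate/virulent lifestyle calling from
  integrase/recombinase/CI-repressor gene content.
* **Abundance profiles** — coverage-breadth filtering (counts zeroed below
  75% breadth), RPKM transformation, and aggregation of vOTUs by predicted
  bacterial host.
* **Community dynamics** — Shannon diversity, Bray–Curtis dissimilarity,
  retention of baseline vOTUs over time, the persistent/transient virome
  partition (PPV: present in ≥75% of an individual's samples), temperate
  phage abundance fractions, and bootstrap CIs.
* **Strain distances** — Kimura 2-parameter distances on trimmed consensus
  alignments, with per-pair deletion of ambiguous sites and per-entity
  median normalisation.
* **Transmission inference** — a one-sided Wilcoxon rank-sum comparison of
  related vs unrelated mother–infant strain distances with a
  label-permutation null, Benjamini–Hochberg FDR, kernel-Youden
  strain-identity cutpoints with an empirical-FDR fallback, strain-sharing
  calls, Fisher enrichment, and pre-/post-birth timing.
* **Co-transmission** — partial Mantel tests between phage and host
  strain-sharing matrices (controlling for repeated sampling of
  individuals) and the "non-random linkage" statistic
  Δ = f_obs − f_exp with a chi-squared test.
* **Synthetic cohorts** — a generator that evolves strain sequences under
  the K80 substitution model on family trees, with planted transmission and
  phage–host coupling, so every inference stage can be validated against
  known truth.

## The core statistics

Strain distances use the Kimura two-parameter model. For a pair of aligned
sequences with transition proportion *P* (A↔G, C↔T) and transversion
proportion *Q* over the comparable sites,

    d = −½ ln( (1 − 2P − Q) √(1 − 2Q) )

Distances are normalised per entity by the median within-individual
(longitudinal) distance, so that a common strain-identity scale applies
across entities. The identity cutpoint maximises the kernel-smoothed Youden
index J(t) = TPR(t) + TNR(t) − 1, where within-individual distances are
positives and unrelated-pair distances negatives; if that threshold would
admit more than 5% of unrelated pairs, the 5th percentile of the unrelated
distances is used instead (empirical FDR). A normalised distance below the
cutpoint is a strain-sharing event.

Transmission per entity is tested by permuting the related/unrelated labels
over mother–infant sample pairs (the groups are highly unequal in size) and
comparing one-sided Wilcoxon rank-sum statistics. Co-transmission of a
phage with its predicted host is tested on binarised sharing matrices over
concurrent samples with a partial Mantel correlation given a
same-individual control matrix, plus the non-random linkage excess
Δ = f_obs − f_exp of joint sharing over independence.

## Worked example

```bash
python examples/strain_transmission.py
```

runs the full pipeline on a six-family synthetic cohort with ten vOTUs, a
50% transmission rate and strong distance separation (d_within = 0.002,
d_transmit = 0.005, d_unrelated = 0.1 substitutions/site), and prints:

```
entity_id  p_perm      q  share_rate_related  share_rate_unrelated  n_events cutpoint_method  transmitted_call
 vOTU0000  0.0010 0.0017                 1.0                   0.0       125   youden_kernel              True
 vOTU0001  0.2917 0.3646                 0.0                   0.0         0   youden_kernel             False
 ...
confusion vs planted truth: {'tp': 9, 'fp': 1, 'fn': 0, 'tn': 5}
```

`p_perm` is the label-permutation p-value for "related mother–infant strain
distances are smaller than unrelated ones", `q` its BH adjustment; a
transmitted call means q < 0.05. `n_events` counts related sample pairs
whose normalised distance fell below the entity's strain-identity cutpoint.
The confusion line scores the calls against the cohort's planted truth
table. Other example scripts cover cohort simulation
(`simulate_cohort.py`), community dynamics (`virome_dynamics.py`), the
curation rules (`curation_rules.py`) and phage–host co-transmission
(`cotransmission.py`).

A thin CLI wraps the same stages:

```bash
virotrace simulate --seed 7 --out cohort/
virotrace curate cohort/annotations.tsv --out curated.tsv
virotrace transmit cohort/ --out transmission.tsv
```

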