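# Methods

This note describes the models and procedures implemented in `virotrace`,
the choices made where the design was genuinely open, and what the
synthetic-data experiments do and do not demonstrate.

## Scaffold curation

Curation consumes precomputed per-scaffold annotation features (BLAST, HMM,
VirSorter, CheckV, vConTACT2 and negative-control dereplication outputs
arrive as a TSV; running those tools is out of scope). Three stages:

1. **Inclusion.** A scaffold ≥1 kbp is putatively viral if at least one of
   six criteria holds: (1) a RefSeq-viral BLAST hit; (2) ≥3 ORFs with pVOG
   HMM hits at a density ≥2 per 10 kb; (3) VirSorter-positive (any
   category, including suggestive); (4) circular; (5) a *Crassvirales*
   hit; (6) longer than 3 kbp with no nt-database hit ("viral dark
   matter"). Boundary conventions: "at least three ORFs" is `pvog_hits >=
   3`; "longer than 3 kbp" is strict (`> 3000`); the density
   `pvog_per_10kb = pvog_hits / (length_bp/1e4)` is compared with ≥2 for
   inclusion but <3 for condemnation below — the two densities are
   deliberately different screens.
2. **Negative-control dereplication.** Any scaffold whose 99%-ANI cluster
   contains a scaffold assembled from a negative control is discarded.
3. **Genus-cluster (VC) decontamination.** A VC is condemned when any
   member (a) carries an rRNA gene, (b) carries ≥1 ribosomal protein gene
   with <3 pVOGs per 10 kb and is neither VirSorter-positive nor circular,
   or (c) carries >3 ribosomal protein genes. Members of condemned VCs are
   rescued individually when (r1) circular with ≥1 pVOG, (r2) circular and
   VirSorter-positive, or (r3) VirSorter-positive with no ribosomal
   proteins. Rescue rule r3 can overlap condemnation rule (b) for the same
   member; here rescue wins for that member — the rescue list is read as a
   whitelist applied after VC-level condemnation.

**Lifestyle.** A phage is temperate iff it carries an integrase gene, or a
recombinase gene together with a CI-repressor-like gene; the call depends
on nothing else.

**Strain candidates.** Strain-level analysis is restricted to vOTUs with a
CheckV high-quality/complete or circularised genome, length ≥3 kbp, and
presence (coverage breadth strictly >0.95) in both a maternal and an
infant sample of the same family for ≥5 distinct families. Sharedness is
required within families because the downstream question is
mother-to-infant transmission.

## Abundance profiles

Read counts per (scaffold, sample) are zeroed when the scaffold's coverage
breadth is below 0.75 (spurious-alignment filter; a record exactly at the
threshold is retained — the rule is "less than"). Counts then become RPKM
= count / (length/10³) / (library/10⁶). The library size is the
per-sample total of mapped reads supplied in the metadata; any consistent
per-sample total works since downstream statistics are scale-free per
sample. Host-level profiles sum vOTU RPKM by the single highest-confidence
predicted host; unmapped vOTUs are collected under `unassigned`, so
aggregation conserves per-sample totals.

## Community dynamics

Shannon diversity uses natural logarithms (the ecology-package default).
Bray–Curtis is Σ|x−y| / Σ(x+y). Retention metrics compare a baseline and a
later sample of the same subject: the retained count, the share of the
*later* sample's richness that was already present at baseline, and the
share of the later sample's abundance carried by retained entities. The
persistent/transient partition (PPV/TDV) assigns an entity to the PPV when
it is present in ≥75% of a subject's samples (so 3 of 4 qualifies);
subjects with fewer than 3 samples are skipped. Bootstrap CIs for means
resample with replacement (default 1000 replicates) and report the
empirical 0.025/0.975 quantiles with linear (type-7) interpolation.

## Strain distances

Per-entity consensus alignments are end-trimmed by 100 bp (global
alignments accumulate gaps at the flanks) and all pairwise distances are
computed under the K80 model: with transition proportion P and
transversion proportion Q over comparable sites,
d = −½ ln((1−2P−Q)√(1−2Q)). Sites where either member of a pair carries a
gap or N are deleted **per pair** — the default of classic distance tools
(drop a column when *any* record is ambiguous) wastes signal in sparse
consensus alignments; complete deletion remains available via
`deletion="complete"` for strict replication. Pairs outside the model's
valid region (1−2P−Q ≤ 0 or 1−2Q ≤ 0) are saturated: they propagate as
NaN, are excluded from all tests, and are counted in warnings.

Distances are normalised by a per-entity median so cutpoints share a
scale. The normaliser is the median of within-individual (longitudinal)
distances, pooling mothers and infants, because within-person strain drift
is the natural unit of "same strain" variation; entities with no
within-individual pair fall back to the median of all finite distances.
Both conventions are exposed, since either median can be defended and the
choice only rescales the cutpoint together with the distances.

## Transmission inference

Per entity, sample pairs are labelled `within_individual`, `related`
(mother–infant, same family), or `unrelated` (mother–infant, different
families); other combinations (mother–mother, infant–infant) carry no
information about mother-to-infant transmission and are excluded. The
distance comparison is a one-sided Wilcoxon rank-sum ("related distances
are smaller") whose significance comes from permuting the
related/unrelated labels over pairs — the group sizes are extremely
unequal, and the permutation null respects them exactly. Small problems
(≤2·10⁵ label assignments) are enumerated exhaustively
(p = #{S ≤ S_obs}/N); larger ones use 1000 Monte-Carlo draws with the
standard (1+hits)/(n+1) estimate. P-values are BH-adjusted across
entities; a transmitted call means q < 0.05.

**A caveat on pair-level permutation.** Distances that share a sample are
dependent (a long branch on one strain shifts every pair it enters), and a
label permutation over pairs ignores this. In the pooled design the
dependence acts *conservatively*: shared shifts cancel between the related
and unrelated groups, so the test under-rejects but does not inflate type
I error. The calibration experiment in `virotrace.experiments` therefore
measures type-I error on a focal design in which each pair is an
exchangeable unit — one infant sample against a single sample from each of
20 mothers, the infant's own mother forming the one related pair — where
the p-value is provably uniform; the pooled design is checked separately
for the one-sided property (never exceeding the nominal level). The same
dependence caveat applies to the Fisher sharing tests, as in the original
formulation; it is accepted there for comparability.

**Cutpoints.** Within-individual normalised distances are positives,
unrelated-pair distances negatives. Gaussian KDEs (Silverman bandwidth) of
both groups are evaluated on a 512-point grid over the pooled range, and
the threshold maximises the smoothed Youden index J(t) = TPR(t) + TNR(t) −
1, taking the middle of any plateau (well-separated groups have a wide
flat optimum; the midpoint is the stable, symmetric choice). If the
empirical fraction of unrelated pairs admitted below the threshold exceeds
5%, the threshold is replaced by the 5th percentile (type-7) of the
unrelated distances — the empirical-FDR fallback. The gate is read as
"admit rate > 5%"; the alternative reading (fall back when J itself
exceeds 0.05) is implemented behind `youden_gate=True`. A zero-variance
group degenerates the KDE; the midpoint between the group extremes is used
with a warning.

**Sharing calls.** A pair shares a strain when its normalised distance is
strictly below the cutpoint; a pair exactly at the cutpoint is *not*
shared (the rule is strict on both sides, so equality resolves to the
conservative side). Sharing enrichment in related pairs and the
pre-/post-birth comparison (related pairs split by the maternal sample's
class: pregnancy/birth vs months 1–3 postpartum) use one-sided Fisher
tests with BH adjustment.

## Co-transmission

For each virus–bacterium pair, analysis runs on concurrent
(individual, timepoint) units where both strains were reconstructed —
viral strains from VLP metaviromes with MGS fallback (VLP preferred when
both exist for a unit), bacterial strains from total metagenomes. Sharing
calls are binarised with 0 = shared, and a control matrix C marks pairs of
units from the same individual (a mother and her infant are different
individuals). Pairs with fewer than 4 units are skipped.

The partial Mantel statistic is the residual-form partial Pearson
correlation r_M = (r_vb − r_vc·r_bc)/√((1−r_vc²)(1−r_bc²)) on vectorised
upper triangles, with a one-sided null built by simultaneously permuting
rows and columns of the virus matrix (999 permutations; ≤7 units are
enumerated exhaustively). Permutations whose statistic is undefined (a
permuted matrix collinear with C) are excluded from the null. When virus
and bacterium matrices are mutually collinear the partial correlation
degenerates and a simple Mantel is used; when either matrix is collinear
with C the pair is skipped, since the repeated-measures control cannot be
applied.

Non-random linkage is Δ = f_obs − f_exp over unordered unit pairs, with
f_obs the fraction of pairs where both strains are shared and f_exp the
product of the marginal sharing fractions; significance comes from a
chi-squared test of independence without continuity correction (expected
counts <5 raise a warning, not a method switch). "Proportion of concurrent
samples" is interpreted at the pair level, because sharing is a pairwise
object. A pair is flagged co-transmitted when its BH-adjusted Mantel p is
<0.05 and Δ > 0. Host-vs-random enrichment compares co-transmission
frequencies between true virus–host pairs and random virus–bacterium
pairs with a one-sided Fisher test.

## Synthetic cohorts

The generator emulates the sampling design of a longitudinal mother–infant
virome study: families of one mother (samples at pregnancy months 3 and 7,
birth, and months 1–3 postpartum) and 1–2 infants (months 1–12), VLP
metaviromes alongside total metagenomes (no week-12 maternal or month-9
infant VLP library), uniform random dropout with a guarantee that no
individual loses all samples, log-normal abundances with mother/infant
compositional offsets and a temperate-phage skew toward infants, and
annotation features consistent with the planted lifestyle labels.

Strain sequences evolve under continuous-time K80 with analytic transition
probabilities, so the expected re-estimated K2P distance equals the target
exactly (per-site substitution categories are drawn from the model's
P(t), Q(t) at the requested distance; the transition/transversion rate
ratio κ defaults to 2). Each entity has a root sequence; family ancestors
sit at d_unrelated/2 from the root; each individual's base strain hangs
d_transmit/2 below the family ancestor (transmitted entities and all
mothers) or below a private ancestor at the same depth (non-transmitted
infants); every sample drifts d_within/2 from the individual's base. By
branch additivity, related transmitted pairs differ by ≈ d_transmit +
d_within, longitudinal pairs by ≈ d_within, and everything else by
≈ d_unrelated, while under no transmission related and unrelated pairs
have identical expectations — the exchangeable null the calibration
experiments rely on.

Transmission is planted per entity: a transmitted vOTU carries related
strains in every family where it appears. This gives each vOTU one clean
transmitted/not-transmitted truth label, which is what the
sensitivity/false-discovery experiments score; per-family mosaic
transmission would leave almost no true negatives at realistic rates. When
a transmitted phage is coupled to its predicted host (probability
`coupling_rate`), the host strain is forced transmitted and reconstructed
in exactly the phage's units, planting the co-transmission signal.
Background vOTUs — abundance-only community members with no strain
alignments, including a fraction of negative-control contaminants and
rRNA-carrying cellular scaffolds — provide realistic presence/absence
turnover for the community metrics and genuine material for the curation
stage.

Default distances are d_within = 0.002, d_transmit = 0.005, d_unrelated =
0.1 substitutions/site. No field data constrain these values directly;
they were chosen once so that within-individual drift, transmission
divergence and between-family divergence are separated on the scale real
strain comparisons show (within ≪ between), and they are not tuned.
Defaults of 6 families and 10–20 kb sequences keep desk-scale experiments
fast; the study this emulates had 30 families and scaffolds from 1 to
476 kbp.

What the synthetic cohort does **not** emulate: assembly or consensus
errors, coverage-dependent missingness of strains (strain recovery is
all-or-nothing per sample), recombination, within-sample strain mixtures
(consensus = dominant strain), MGS/VLP disagreement, and compositional
count noise. Passing tests therefore demonstrate correctness of the
inference machinery under the stated generative model, not robustness to
every artefact of real metavirome data.

## Validation experiments and problem sizes

`virotrace.experiments` contains the calibration/recovery studies used by
the test suite and `scripts/acceptance.py`:

* `permutation_typeI_experiment` — 500 null entities, 20 families, 2 kb
  sequences, focal exchangeable design; rejection at α = 0.05 should sit
  near 0.05.
* `pooled_typeI_experiment` — the pooled design's (conservative) rejection
  rate.
* `linkage_null_experiment` / `mantel_typeI_experiment` — Δ and partial
  Mantel on independently drawn symmetric binary matrices. These nulls use
  directly simulated matrices because in a shared-family cohort two
  transmitted-but-uncoupled entities have correlated sharing patterns by
  construction — the very confounding the host-vs-random comparison
  exists to address — so cohort-derived "uncoupled" pairs are not a clean
  independence null.
* `parameter_recovery_experiment` — the full pipeline on a 40-vOTU cohort
  (50% transmission, full coupling, 20 kb sequences, 6 families, 10%
  dropout), scored against the planted truth for sensitivity,
  false-discovery proportion and co-transmission detection.

These sizes keep any single experiment under about a minute on one CPU
while leaving Monte-Carlo error small relative to the properties asserted.

## Numerical conventions

* Ties at the sharing cutpoint → not shared; ties in the Youden grid →
  plateau midpoint; rank ties → average ranks.
* Quantiles (bootstrap, empirical FDR) use linear type-7 interpolation.
* Permutation p-values: exhaustive enumeration counts the identity
  assignment (p ≥ 1/N); Monte-Carlo estimates use (1 + hits)/(n + 1).
* One global seed fans out to per-stage and per-entity child generators
  via `numpy.random.Generator.spawn`, so outputs are reproducible and
  insensitive to iteration order changes elsewhere.
* Config validation is explicit (typed range checks with named errors) on
  the YAML run configuration; every output directory receives the
  serialized config and a JSON run report accounting for all filtered
  records.

## Known limitations

* The Fisher sharing/enrichment tests treat pairs as independent although
  pairs sharing a sample are not; kept for comparability with the standard
  formulation and flagged here.
* The pooled permutation test is conservative under pair dependence (see
  above); effect sizes on the distance scale, not only p-values, should be
  reported for borderline entities.
* Chi-squared linkage p-values are asymptotic and rough below ~5 expected
  counts per cell.
* Directionality (mother→infant rather than infant→mother or common
  source) is assumed, not inferred.
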