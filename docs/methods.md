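# Methods

## The detection problem

Sign epistasis — gene action in which an allele is beneficial or detrimental
depending on the allelic state of an interacting locus — leaves a
characteristic footprint in a closed breeding program. Selection acts on
allelic *combinations*, so two interacting loci on different chromosomes stay
statistically associated even though independent assortment reshuffles them at
every meiosis. Persistent, strong **interchromosomal linkage disequilibrium**
(LD) is therefore a candidate selection signature. The difficulty is that
population structure, genetic drift in small families, and additive selection
can each produce strong pairwise LD on their own. `signepi` implements a
screening-and-falsification procedure that addresses each confounder in turn,
plus a forward-in-time breeding simulator that supplies the drift null and
planted-truth panels for end-to-end verification.

## Discovery: the two-stage screen

LD is measured as r², the squared Pearson correlation of alternate-allele
dosages (see *Estimator* below). The screen considers only marker pairs on
different chromosomes, restricted to markers with pooled minor allele
frequency above `maf_min_discovery` (default 0.30, strict `>`): balanced
frequencies are where a sign-epistasis signal is visible, and the restriction
shrinks the pair universe.

1. **Per-family stage** (controls population structure): r² is computed inside
   each biparental family separately; a pair is noted when r² > `r2_family`
   (default 0.9). A family in which either marker is monomorphic contributes
   *undefined* — it neither passes nor vetoes.
2. **Combined stage** (controls drift): the same pairs must show
   r² > `r2_combined` (default 0.8) on all families pooled. Drift generates
   strong within-family LD with *random phase*; when families are pooled,
   opposite-phase associations cancel and pooled r² collapses. Only selection,
   which aligns the phase across families, survives both stages.

A candidate must pass the family stage in at least `min_families` (default 2)
families *and* the combined stage. Thresholds use strict inequalities
throughout. Undefined (NaN) values fail every threshold — three-valued logic
with no silent coercion to 0.

Candidate markers are grouped into **regions** per chromosome by
single-linkage clustering with a physical gap of at most `region_gap_bp`
(default 10 Mb). The procedure that produced the published region counts is
not described at this granularity; with a typical genotyping-by-sequencing
marker density (~1 marker / 300 kb) and the large LD blocks that balancing
selection drags along, physical distance is the only available criterion, and
the gap is exposed in configuration. Region pairs connected by candidate
marker pairs form **interactions**; triangles of regions on three distinct
chromosomes are additionally reported as 3-way candidates (clique detection on
the region graph), alongside their pairwise components.

Sample QC precedes screening: within each family, samples are projected on the
first two principal components of the centered dosage matrix and removed when
their distance from the family centroid exceeds `outlier_sd` (default 3.0)
times the root-mean-square distance, capped at 20% of the family. This guards
against mislabeled or contaminated lines that would masquerade as structure.

## Falsification: allelic-combination analysis

For each interaction, the k = 2 or 3 representative loci define 2^k homozygous
allele-combination classes. The **favored** combination is the most frequent
one (ties broken lexicographically, so labels are deterministic); the
**opposed** combination is its allele-wise complement; everything else is an
**off-combination**. Under sign epistasis both favored and opposed persist at
high frequency while off-combinations are purged; under additive selection one
combination sweeps and its complement decays; under drift the pattern is
incoherent across families.

Family tables are classified in rule order: heterozygote share above
`het_inconclusive_share` (0.30) → inconclusive; an off-combination most
frequent in a *fixed* family (top share ≥ `fixation_threshold`, 0.95) →
parental off-fixation, which is tolerated (the family's parents simply carried
the off-combination, so the favored classes could never appear); an
off-combination most frequent in a *segregating* family → grounds for
rejection; favored and opposed both at ≥ 10% → the sign-epistasis
opposed-pair pattern; otherwise a single-dominant or
predominant-with-opposed call. The fixed/segregating distinction is applied
with an explicit numeric threshold (0.95) where the original argument was
narrative.

Three falsification rules then act on each candidate:

* **independent families** — any segregating validation family dominated by an
  off-combination rejects the interaction;
* **breeding-program share** — pooled over a decade of program lines, an
  opposed-combination share below `opposite_min_share` (0.10, strict `<`) of
  called samples rejects it (drift, not balancing selection, explains the
  discovery pattern). The denominator is all called samples (homozygous
  classes plus heterozygotes), excluding missing and imputed entries — the
  printed rule does not define its denominator, and this is the conservative
  choice;
* **single-marker regions** — an interaction resting on a region with exactly
  one marker is rejected: in a large repetitive polyploid genome a lone
  GBS marker can owe its LD to read misalignment rather than biology.

Stage tracking computes the combination shares separately for the sequential
yield-trial stages (IPSR → PYN → AYN → EYN); under selection against
off-combinations the off share declines along the pipeline. The
observed-vs-expected comparison uses a linkage-equilibrium product of each
locus's *homozygote* marginal shares, renormalized over the homozygous
classes, rather than literal Hardy–Weinberg proportions: selfed lines are far
from panmixia, and preserving the observed inbreeding is the meaningful null.

## The r² estimator

`pairwise_r2` is the squared Pearson correlation of dosages on the pairwise-
complete mask — exactly what it is handed, with no recoding. On fully
homozygous panels this equals the classical haplotype-frequency
r² = D²/(p_A p_a p_B p_b) (each inbred line contributes two identical
haplotypes); `haplotype_r2` implements the haplotype-counting form by direct
2×2 counting and serves as an independent cross-check in the tests, never as
the screening implementation.

The *screens* (per-family, combined, interchromosomal scan, flanking windows)
mask residual heterozygous calls as missing before correlating
(`ld_het_as_missing`, default on). Two reasons. First, in F5-derived lines a
heterozygous GBS call is phase-ambiguous and disproportionately a genotyping
error, and standard inbred-panel practice drops such calls for LD purposes.
Second, and specific to the biology here: strong viability selection against
off-combination *homozygotes* makes the selected loci behave like a balanced
lethal system. Each generation, the off-combination offspring of heterozygous
plants die and are effectively replaced, so heterozygosity at the interacting
loci decays far more slowly than the neutral halving per selfing generation
(up to ~40% of F5 lines heterozygous at one of the planted loci in simulation,
against 12% neutrally when heterozygote fitness is unaffected). Including
those dosage-1 values biases the correlation downward precisely at true
positives, while the association among homozygous calls is exact. Combination
*counting* is unaffected by the mask — heterozygotes are tabulated as their
own class there, which is also why a heterozygote-inconclusive label exists.

Monomorphic markers yield undefined r² and are silently skipped by scans;
an "interchromosomal block" is a run of ≥ `block_min_run` (3) consecutive
flanking markers whose best cross-window r² exceeds `block_r2` (0.5) —
published block evidence is graphical, so both values are configuration, not
doctrine. Flanking windows take `n_flank_per_side` = 20 markers per side
(reading "40 flanking markers" as a whole-window count; the per-side reading
is one config value away).

## The breeding simulator

The simulator is the synthetic-data module: it defines the study conditions
for the null and recovery experiments.

* **Map** — 21 chromosomes labeled 1A–7D, 1.5 Morgans each, markers uniformly
  spaced (default 200 per chromosome, 4,200 total), physical positions on a
  fixed 5 Mb/cM scale. Meiosis draws a Poisson(length) crossover count with
  uniform breakpoints and no interference (Haldane model); interference is
  irrelevant for interchromosomal pairs, which is where all inference happens.
* **Founders** — fully inbred; per-marker alternate-allele frequencies drawn
  uniformly from `maf_spectrum` (default 0.1–0.5, which leaves roughly half
  the markers, ~2,000, above the 0.30 discovery screen after pooling). Loci
  are independent by default; an optional mosaic mode builds founder
  haplotypes as crossover mosaics of a small ancestral pool when
  intrachromosomal founder LD is wanted.
* **Crosses and selfing** — families are 1-way (biparental) or 3-way
  ((P1×P2)×P3) crosses of distinct founders, default an even mix. Each family
  draws `family_size` independent F2 individuals from the selfed F1 and
  advances each by single seed descent to `final_generation` (default F5,
  i.e. four selfing rounds past the F1; an F6 switch exists since empirical
  lines are often genotyped as F5:6 bulks).
* **Viability selection** — epistatic mode: an off-combination homozygote
  survives with probability 1−s; a plant heterozygous at any model locus with
  probability 1−h·s; both favored homozygote classes are untouched. Additive
  mode: survival (1−s) per unfavored allele at a single locus. s = 0
  reproduces the neutral model stream-for-stream (no random draws are
  consumed), so the reduction is exact, not just distributional. A dead draw
  is replaced, within a redraw budget (default 10 × family size); the death
  count is reported as attrition — the effective-population-size cost that
  strong epistatic selection inflicts on a cross — and budget exhaustion is an
  error rather than a silent rescue.
* **Randomness** — one root seed; founder and per-family generators are
  spawned from a `SeedSequence`, so every output is bit-reproducible and
  families are independent streams.

**What the generator does and does not emulate.** It produces
mostly-homozygous F5 families of realistic size with residual heterozygosity,
drift, and optional planted selection — the features the screening procedure
actually exercises. It does not emulate genotyping error, missing calls,
founder-pool relatedness or structure, intrachromosomal founder LD (unless
mosaic mode is on), or marker ascertainment. Passing tests therefore show the
procedure's behavior under clean genotypes at the stated design; on real GBS
data the pipeline-level marker filters (MAF < 0.01, > 20% missing, > 20%
heterozygous, mean imputation) and the PCA sample QC carry the weight the
generator omits.

## Experiments and problem sizes

`drift_null_experiment` simulates 100 families (15 lines, mixed cross types,
no selection), pushes the pooled panel through the *full* candidate criteria,
and reports the candidate count plus the per-family and pooled r²
distributions restricted to pairs polymorphic in ≥ 2 families. At these sizes
a drift-only run yields pooled interchromosomal r² maxima around 0.13 —
nowhere near the 0.8 criterion — and zero candidates across seeds, while
single families routinely contain perfect-LD pairs: the two-stage design, not
either stage alone, is what kills drift.

`planted_epistasis_experiment` fixes half the founder pool for one favored
combination and half for its complement, crosses across the groups (10
families of 20 by default, 1-way), applies lethal epistatic selection
(s=1, h=0), and runs discovery plus combination analysis end to end. The
planted pair is recovered as the sole candidate and read as an opposed pair in
multiple families; with additive selection planted instead, the pair is never
nominated (no interchromosomal LD arises) or is rejected by the opposed-share
rule. Acceptance-scale checks use 5 drift seeds, 20 planted replicates, and
5 additive controls; simulator invariants use 400 lines (F5 heterozygosity
1/16), 4,000 F2 plants (7/8 survival under s=1), and 10,000 gametes
(recombination fraction (1−e⁻¹)/2 ≈ 0.316 at 0.5 Morgans). These sizes make
binomial noise small against the tested margins.

## Known limitations

* Dosage-correlation r² (even het-masked) is not PLINK's EM haplotype r²;
  on highly heterozygous or poorly imputed data the two diverge, so exact
  reproduction of counts derived with other tools may require matching the
  estimator.
* Region grouping is physical-distance single linkage; counts of "regions"
  are sensitive to the gap parameter, and no significance is attached to
  region boundaries.
* The procedure uses fixed thresholds, not hypothesis tests; it inherits the
  published design's choice to argue by pattern consistency and falsification
  rather than p-values.
* The fixed/segregating distinction (`fixation_threshold`) and the
  heterozygote-inconclusive rule (`het_inconclusive_share`) quantify
  qualitative judgments; both are configurable and results near those
  boundaries should be read accordingly.
* 3-way candidates are assembled from pairwise evidence (region triangles);
  no genuinely trivariate statistic is computed.
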