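# signepi

Detection of **sign-epistasis selection signatures** in inbred breeding
families via **interchromosomal linkage disequilibrium (LD)** — with a
forward-in-time breeding simulator supplying the genetic-drift null and
planted-truth panels.

Written for quantitative geneticists and breeders working with
genotyping-by-sequencing panels of mostly-homozygous lines (e.g. F5-derived
wheat breeding families), where elite × elite crosses sometimes collapse
because the parents carry *different* co-adapted allele combinations.

## The idea

Under sign epistasis, selection favors allelic *combinations* rather than
alleles: two complementary homozygous combinations at interacting loci (say
A/T and C/C) confer similar adaptation, while the mixed "off-combinations"
(A/C, C/T) are deleterious. Continuous selection then maintains a statistical
association between the loci even when they sit on different chromosomes,
where independent assortment should erase it each meiosis.

`signepi` measures that association as

r² = corr(x_A, x_B)²,

the squared Pearson correlation of alternate-allele dosages (equal to the
classical haplotype-frequency r² = D²/(p_A p_a p_B p_b) on inbred lines), and
applies a two-stage screen:

1. within each family, keep interchromosomal pairs with r² > 0.9
   (population structure cannot act inside a biparental family);
2. across all families pooled, require r² > 0.8 (drift produces strong
   within-family LD with *random phase*, which cancels when families are
   pooled — only selection aligns the phase);

with a candidate needing stage 1 in ≥ 2 families plus stage 2. Candidates are
then falsified by allelic-combination frequencies: independent validation
families whose most frequent class is an off-combination, an
opposed-combination share below 10% of the pooled breeding program, or an
interaction resting on a single marker (a likely alignment artifact) each
reject a candidate. The breeding simulator (1- and 3-way crosses, single seed
descent to F5, Poisson/Haldane recombination, optional viability selection
against off-combinations) provides the drift-null comparison demonstrating
that the criteria are unreachable by drift alone.

See `docs/methods.md` for the full model, parameter meanings, and design
choices.

## Worked example

Plant a lethal two-locus sign-epistasis interaction (s = 1) in 10 simulated
families of 20 F5 lines and run discovery plus classification end to end:

```python
from signepi.breeding_sim import planted_epistasis_experiment

report = planted_epistasis_experiment(seed=3)
print("planted loci:   ", report.planted_loci)
print("recovered:      ", report.recovered, f"({report.n_candidates} candidate)")
print("favored/opposed:", "/".join(report.pooled_favored), "vs", "/".join(report.pooled_opposed))
print("opposed-pair families:", report.n_opposed_pair_families, "of", len(report.family_patterns))
print("program opposed share:", round(report.program_share.evidence["opposed_share"], 3))
```

```
planted loci:    ('1A_0100', '4A_0100')
recovered:       True (1 candidate)
favored/opposed: C/C vs T/T
opposed-pair families: 6 of 10
program opposed share: 0.335
```

The planted pair is the *only* candidate the screen nominates, its two
complementary combinations are both common (the opposed share of 0.335 is far
above the 10% rejection line), and 6 of 10 families individually show the
opposed-pair pattern; the remaining families are heterozygote-inconclusive —
with lethal selection against off-combination homozygotes and unaffected
heterozygotes, the interacting loci behave like a balanced lethal system and
retain elevated residual heterozygosity (see `docs/methods.md`).

The same pipeline on a drift-only simulation (100 crosses, 15 lines each)
returns zero candidates:

```python
from signepi.breeding_sim import SimConfig, drift_null_experiment

report = drift_null_experiment(SimConfig(seed=1))
print(report.n_candidates, report.n_markers_screened, round(report.max_pooled_r2, 3))
# 0 2020 0.131
```

Single families contain perfect-LD pairs by drift (max family r² = 1.0), but
the pooled maximum (0.13) is nowhere near the 0.8 criterion.

## Command line

```bash
signepi simulate planted --seed 3 --out planted.json
signepi simulate drift-null --seed 1 --out drift.json
signepi discover --panel fam.hmp.txt --meta fam.meta.tsv --out-dir disc/
signepi validate --interactions disc/interactions.tsv \
    --validation-panel val.hmp.txt --validation-meta val.meta.tsv \
    --program-panel prog.hmp.txt --program-meta prog.meta.tsv --out-dir verdicts/
```

Inputs are plain-text HapMap genotype files (`.hmp.txt`) plus a tab-separated
sample-metadata file (`sample_id`, `family_id`, `stage`, `panel`); outputs are
tab-separated tables and a JSON run manifest with content digests.

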