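"""Forward-in-time simulator of inbred breeding families.

Families are founded as 1-way (biparental) or 3-way crosses of fully inbred
founders and advanced by single seed descent (SSD, one selfed offspring per
line per generation) to the F5, with Poisson crossovers under the Haldane
(no-interference) map. Optional viability selection removes individuals
carrying unfavorable allelic combinations at planted epistatic loci (or
unfavored alleles at a single additive locus) at every generation transition.

The simulator supplies the drift-null comparison for the interchromosomal-LD
discovery screen — families evolving under drift alone, pushed through the
full candidate criteria — and planted-selection panels for end-to-end
recovery experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .config import AnalysisConfig
from .genotype_io import (
    CHROMOSOMES,
    GenotypePanel,
    MarkerRecord,
    SampleRecord,
)

__all__ = [
    "GeneticMap",
    "IndividualGenome",
    "SelectionModel",
    "SimConfig",
    "AttritionError",
    "default_wheat_map",
    "synth_founders",
    "sample_crossover_positions",
    "meiosis_gamete",
    "make_cross",
    "self_once",
    "survival_probability",
    "apply_viability_selection",
    "single_seed_descent",
    "self_to_generation",
    "cohort_to_panel",
    "simulate_families",
    "drift_null_experiment",
    "planted_epistasis_experiment",
    "DriftNullReport",
    "PlantedReport",
]

_ALLELE_PAIRS = (("A", "C"), ("A", "G"), ("A", "T"), ("C", "G"), ("C", "T"), ("G", "T"))


class AttritionError(RuntimeError):
    """Raised when viability selection kills more lineages than the redraw budget."""


@dataclass
class GeneticMap:
    """Marker map: genetic positions (Morgans) and physical positions (bp).

    Genetic and physical orders agree within each chromosome; dosage panels
    exported from the simulator inherit chromosome labels and positions here.
    """

    chrom_labels: list[str]
    chrom_lengths: list[float]  # Morgans
    genetic_pos: list[np.ndarray]  # per chromosome, Morgans
    physical_pos: list[np.ndarray]  # per chromosome, bp
    marker_ids: list[list[str]]
    allele_pairs: list[list[tuple[str, str]]]  # (ref, alt) per marker

    def __post_init__(self) -> None:
        self._locus_index: dict[str, tuple[int, int]] = {}
        for ci, ids in enumerate(self.marker_ids):
            g = self.genetic_pos[ci]
            p = self.physical_pos[ci]
            if np.any(g < 0) or np.any(g > self.chrom_lengths[ci]):
                raise ValueError(f"{self.chrom_labels[ci]}: genetic positions outside map length")
            if np.any(np.diff(g) < 0) or np.any(np.diff(p) < 0):
                raise ValueError(f"{self.chrom_labels[ci]}: marker order must be monotone")
            for mi, mid in enumerate(ids):
                self._locus_index[mid] = (ci, mi)

    @property
    def n_chromosomes(self) -> int:
        return len(self.chrom_labels)

    @property
    def n_markers(self) -> int:
        return sum(len(ids) for ids in self.marker_ids)

    def locus(self, marker_id: str) -> tuple[int, int]:
        """(chromosome index, within-chromosome marker index) of a marker."""
        return self._locus_index[marker_id]

    def marker_records(self) -> list[MarkerRecord]:
        out = []
        for ci, chrom in enumerate(self.chrom_labels):
            for mi, mid in enumerate(self.marker_ids[ci]):
                ref, alt = self.allele_pairs[ci][mi]
                out.append(
                    MarkerRecord(mid, chrom, int(self.physical_pos[ci][mi]), ref, alt)
                )
        return out


def default_wheat_map(
    n_markers_per_chrom: int = 200,
    chrom_length_morgans: float = 1.5,
    mb_per_cm: float = 5.0,
    n_chromosomes: int = 21,
) -> GeneticMap:
    """Synthetic map: 21 wheat chromosomes (1A..7D) of 1.5 Morgans each,
    uniformly spaced markers, physical positions on a fixed Mb-per-cM scale."""
    if n_chromosomes > 21:
        raise ValueError("at most 21 labeled chromosomes available")
    labels = list(CHROMOSOMES[:n_chromosomes])
    genetic, physical, ids, alleles = [], [], [], []
    pair_cycle = 0
    for ci, chrom in enumerate(labels):
        g = np.linspace(0.0, chrom_length_morgans, n_markers_per_chrom)
        p = np.round(g * 100.0 * mb_per_cm * 1e6).astype(np.int64) + 1
        genetic.append(g)
        physical.append(p)
        ids.append([f"{chrom}_{i:04d}" for i in range(n_markers_per_chrom)])
        row = []
        for _ in range(n_markers_per_chrom):
            row.append(_ALLELE_PAIRS[pair_cycle % len(_ALLELE_PAIRS)])
            pair_cycle += 1
        alleles.append(row)
    return GeneticMap(labels, [chrom_length_morgans] * n_chromosomes, genetic, physical, ids, alleles)


@dataclass
class IndividualGenome:
    """Two haplotypes per chromosome; each a 0/1 (ref/alt) vector over markers."""

    haplotypes: list[np.ndarray]  # per chromosome, shape (2, n_markers), uint8

    def dosage(self) -> np.ndarray:
        """Alternate-allele counts over all markers, map order, in {0, 1, 2}."""
        return np.concatenate([h.sum(axis=0) for h in self.haplotypes])

    def dosage_at(self, locus: tuple[int, int]) -> int:
        ci, mi = locus
        return int(self.haplotypes[ci][0, mi] + self.haplotypes[ci][1, mi])

    def is_inbred(self) -> bool:
        return all(np.array_equal(h[0], h[1]) for h in self.haplotypes)


@dataclass
class SelectionModel:
    """Viability selection against allelic combinations (or a single allele).

    ``epistatic``: an individual homozygous for a combination outside
    ``favored_combinations`` (allele indices, 0=ref/1=alt) survives with
    probability 1-s; heterozygous at any model locus, with probability 1-h*s.
    ``additive``: survival (1-s)^(count of unfavored alleles at the locus).
    s = 0 reduces to ``none`` behaviorally (and seed-for-seed).
    """

    mode: Literal["none", "epistatic", "additive"] = "none"
    loci: tuple[str, ...] = ()
    favored_combinations: tuple[tuple[int, ...], ...] = ()
    favored_allele: int = 1
    s: float = 0.0
    h: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.s <= 1.0 or not 0.0 <= self.h <= 1.0:
            raise ValueError("s and h must lie in [0, 1]")
        # loci may be left empty and filled in by an experiment helper
        if self.mode == "epistatic" and self.loci:
            if len(self.loci) not in (2, 3):
                raise ValueError("epistatic selection needs 2 or 3 loci")
            for combo in self.favored_combinations:
                if len(combo) != len(self.loci):
                    raise ValueError("favored combination length must match loci")
        if self.mode == "additive" and self.loci and len(self.loci) != 1:
            raise ValueError("additive selection acts on a single locus")


@dataclass
class SimConfig:
    """Breeding-program simulation design.

    Defaults reproduce the drift-null study conditions: 100 crosses, an even
    mix of 1- and 3-way, 15 lines per family, selfed to the F5, founders drawn
    from a synthetic inbred pool whose alternate-allele frequencies follow a
    uniform spectrum.
    """

    n_crosses: int = 100
    family_size: int = 15
    final_generation: int = 5  # F-number; F5 = four selfing rounds past the F1
    cross_mix: tuple[float, float] = (0.5, 0.5)  # (1-way, 3-way)
    n_founders: int = 100
    n_markers_per_chrom: int = 200
    n_chromosomes: int = 21
    chrom_length_morgans: float = 1.5
    mb_per_cm: float = 5.0
    maf_spectrum: tuple[float, float] = (0.1, 0.5)
    n_ancestral_haplotypes: int | None = None  # mosaic founders when set
    selection: SelectionModel = field(default_factory=SelectionModel)
    redraw_budget_factor: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_crosses, self.family_size, self.n_founders) < 0:
            raise ValueError("counts must be non-negative")
        if self.final_generation < 2:
            raise ValueError("final_generation must be at least F2")
        if abs(sum(self.cross_mix) - 1.0) > 1e-9:
            raise ValueError("cross_mix fractions must sum to 1")

    def build_map(self) -> GeneticMap:
        return default_wheat_map(
            self.n_markers_per_chrom,
            self.chrom_length_morgans,
            self.mb_per_cm,
            self.n_chromosomes,
        )


# ---------------------------------------------------------------------------
# Founders and meiosis


def synth_founders(
    config: SimConfig, gmap: GeneticMap, rng: np.random.Generator
) -> list[IndividualGenome]:
    """Fully inbred synthetic founders.

    Per-marker alternate-allele frequencies are drawn uniformly from
    ``maf_spectrum``; each founder's allele is an independent Bernoulli draw,
    doubled into two identical haplotypes. With ``n_ancestral_haplotypes`` set,
    founder haplotypes are instead crossover mosaics of a small ancestral
    haplotype pool, which induces realistic intrachromosomal LD.
    """
    lo, hi = config.maf_spectrum
    freqs = [rng.uniform(lo, hi, size=len(ids)) for ids in gmap.marker_ids]
    if config.n_ancestral_haplotypes is None:
        founders = []
        for _ in range(config.n_founders):
            haps = []
            for ci in range(gmap.n_chromosomes):
                h = (rng.random(freqs[ci].size) < freqs[ci]).astype(np.uint8)
                haps.append(np.vstack([h, h]))
            founders.append(IndividualGenome(haps))
        return founders

    n_anc = config.n_ancestral_haplotypes
    ancestors = [
        [(rng.random(freqs[ci].size) < freqs[ci]).astype(np.uint8) for ci in range(gmap.n_chromosomes)]
        for _ in range(n_anc)
    ]
    founders = []
    for _ in range(config.n_founders):
        haps = []
        for ci in range(gmap.n_chromosomes):
            a, b = rng.integers(n_anc), rng.integers(n_anc)
            h = _recombine(
                ancestors[a][ci], ancestors[b][ci], gmap.genetic_pos[ci],
                gmap.chrom_lengths[ci], rng,
            )
            haps.append(np.vstack([h, h]))
        founders.append(IndividualGenome(haps))
    return founders


def sample_crossover_positions(length_morgans: float, rng: np.random.Generator) -> np.ndarray:
    """Crossover breakpoints on one chromosome: Poisson(length) count,
    uniform positions on genetic coordinates, no interference."""
    k = rng.poisson(length_morgans)
    return np.sort(rng.uniform(0.0, length_morgans, size=k))


def _recombine(
    hap0: np.ndarray,
    hap1: np.ndarray,
    genetic_pos: np.ndarray,
    length: float,
    rng: np.random.Generator,
) -> np.ndarray:
    breaks = sample_crossover_positions(length, rng)
    start = int(rng.integers(2))
    phase = (start + np.searchsorted(breaks, genetic_pos, side="right")) % 2
    return np.where(phase == 0, hap0, hap1).astype(np.uint8)


def meiosis_gamete(
    parent: IndividualGenome, gmap: GeneticMap, rng: np.random.Generator
) -> list[np.ndarray]:
    """One gamete: per chromosome, an alternating mosaic of the parental
    haplotypes with Poisson(length) crossovers (Haldane model)."""
    return [
        _recombine(
            parent.haplotypes[ci][0],
            parent.haplotypes[ci][1],
            gmap.genetic_pos[ci],
            gmap.chrom_lengths[ci],
            rng,
        )
        for ci in range(gmap.n_chromosomes)
    ]


def make_cross(
    parents: Sequence[IndividualGenome],
    cross_type: Literal["one_way", "three_way"],
    gmap: GeneticMap,
    rng: np.random.Generator,
) -> IndividualGenome:
    """F1 of a biparental cross, or the (P1 x P2) x P3 three-way F1."""
    if cross_type == "one_way":
        if len(parents) != 2:
            raise ValueError("one_way cross needs exactly 2 parents")
        g1 = meiosis_gamete(parents[0], gmap, rng)
        g2 = meiosis_gamete(parents[1], gmap, rng)
    elif cross_type == "three_way":
        if len(parents) != 3:
            raise ValueError("three_way cross needs exactly 3 parents")
        f1 = make_cross(parents[:2], "one_way", gmap, rng)
        g1 = meiosis_gamete(f1, gmap, rng)
        g2 = meiosis_gamete(parents[2], gmap, rng)
    else:
        raise ValueError(f"unknown cross type {cross_type!r}")
    return IndividualGenome([np.vstack([a, b]) for a, b in zip(g1, g2)])


def self_once(
    parent: IndividualGenome, gmap: GeneticMap, rng: np.random.Generator
) -> IndividualGenome:
    """One selfed offspring: two independent gametes of the same parent."""
    g1 = meiosis_gamete(parent, gmap, rng)
    g2 = meiosis_gamete(parent, gmap, rng)
    return IndividualGenome([np.vstack([a, b]) for a, b in zip(g1, g2)])


# ---------------------------------------------------------------------------
# Viability selection


def survival_probability(
    individual: IndividualGenome, model: SelectionModel, gmap: GeneticMap
) -> float:
    if model.mode == "none" or model.s == 0.0:
        return 1.0
    loci = [gmap.locus(m) for m in model.loci]
    dosages = [individual.dosage_at(l) for l in loci]
    if model.mode == "epistatic":
        if any(d == 1 for d in dosages):
            return 1.0 - model.h * model.s
        combo = tuple(d // 2 for d in dosages)
        return 1.0 if combo in model.favored_combinations else 1.0 - model.s
    # additive: one locus, per unfavored allele
    d = dosages[0]
    unfavored = (2 - d) if model.favored_allele == 1 else d
    return (1.0 - model.s) ** unfavored


def apply_viability_selection(
    cohort: Sequence[IndividualGenome],
    model: SelectionModel,
    gmap: GeneticMap,
    rng: np.random.Generator,
) -> list[IndividualGenome]:
    """Survivors of one round of viability selection (s=0 is the identity and
    consumes no random draws)."""
    survivors = []
    for ind in cohort:
        p = survival_probability(ind, model, gmap)
        if p >= 1.0 or rng.random() < p:
            survivors.append(ind)
    return survivors


def _surviving_offspring(
    parent: IndividualGenome,
    gmap: GeneticMap,
    model: SelectionModel,
    rng: np.random.Generator,
    budget: dict[str, int],
) -> IndividualGenome:
    while True:
        child = self_once(parent, gmap, rng)
        p = survival_probability(child, model, gmap)
        if p >= 1.0 or rng.random() < p:
            return child
        budget["deaths"] += 1
        if budget["deaths"] > budget["max"]:
            raise AttritionError(
                f"viability selection exhausted the redraw budget "
                f"({budget['max']} deaths); selection too strong for this design"
            )


# ---------------------------------------------------------------------------
# Single seed descent


def single_seed_descent(
    f1: IndividualGenome,
    family_size: int,
    final_generation: int,
    gmap: GeneticMap,
    selection: SelectionModel,
    rng: np.random.Generator,
    redraw_budget: int | None = None,
) -> tuple[list[IndividualGenome], int]:
    """Advance a family from its F1 to ``final_generation`` by SSD.

    ``family_size`` independent F2 individuals are drawn from the selfed F1 and
    each advanced one selfed offspring per generation; viability selection (if
    configured) is applied to every newborn, with dead draws replaced until the
    shared redraw budget (default 10 x family_size) runs out. Returns the final
    cohort and the death count — the attrition that strong selection inflicts
    on the effective family size.
    """
    if final_generation < 2:
        raise ValueError("final_generation must be at least F2")
    budget = {
        "deaths": 0,
        "max": redraw_budget if redraw_budget is not None else 10 * family_size,
    }
    cohort = [
        _surviving_offspring(f1, gmap, selection, rng, budget) for _ in range(family_size)
    ]
    for _ in range(final_generation - 2):  # F2 -> F(final)
        cohort = [
            _surviving_offspring(line, gmap, selection, rng, budget) for line in cohort
        ]
    return cohort, budget["deaths"]


def cohort_to_panel(
    cohort: Sequence[IndividualGenome],
    gmap: GeneticMap,
    family_id: str,
    panel_label: str = "simulated",
    stage: str | None = None,
    sample_prefix: str | None = None,
) -> GenotypePanel:
    """Export a cohort as a genotype panel with integer dosages."""
    markers = gmap.marker_records()
    prefix = sample_prefix if sample_prefix is not None else family_id
    samples = [
        SampleRecord(f"{prefix}_{i:03d}", family_id=family_id, stage=stage, panel=panel_label)
        for i in range(len(cohort))
    ]
    dosage = (
        np.column_stack([ind.dosage() for ind in cohort]).astype(float)
        if cohort
        else np.empty((gmap.n_markers, 0))
    )
    return GenotypePanel.from_parts(markers, samples, dosage)


def self_to_generation(
    f1: IndividualGenome,
    family_size: int,
    final_generation: int,
    gmap: GeneticMap,
    selection: SelectionModel,
    rng: np.random.Generator,
    family_id: str = "fam",
    redraw_budget: int | None = None,
) -> GenotypePanel:
    """SSD advance + panel export (see :func:`single_seed_descent`)."""
    cohort, _ = single_seed_descent(
        f1, family_size, final_generation, gmap, selection, rng, redraw_budget
    )
    return cohort_to_panel(cohort, gmap, family_id)


# ---------------------------------------------------------------------------
# Whole-program simulation


def _concat_panels(panels: Sequence[GenotypePanel]) -> GenotypePanel:
    first = panels[0]
    samples = [s for p in panels for s in p.samples]
    dosage = np.concatenate([p.dosage for p in panels], axis=1)
    mask = np.concatenate([p.imputed_mask for p in panels], axis=1)
    return GenotypePanel(list(first.markers), samples, dosage, mask)


def simulate_families(
    config: SimConfig,
    gmap: GeneticMap | None = None,
    founders: Sequence[IndividualGenome] | None = None,
    parent_groups: tuple[Sequence[int], Sequence[int]] | None = None,
) -> tuple[GenotypePanel, dict]:
    """Simulate ``n_crosses`` families and pool them into one panel.

    Parents are drawn at random from the founder pool (distinct within a
    cross); ``parent_groups`` restricts the first two parents of every cross to
    opposite groups, which is how planted-selection experiments guarantee
    segregating families. Per-family random streams are spawned from
    ``config.seed``, so output is bit-reproducible for a fixed configuration.
    Returns the pooled panel and a per-family info dict (cross type, parents,
    attrition).
    """
    if gmap is None:
        gmap = config.build_map()
    root = np.random.SeedSequence(config.seed)
    founder_seq, *family_seqs = root.spawn(config.n_crosses + 1)
    if founders is None:
        founders = synth_founders(config, gmap, np.random.default_rng(founder_seq))

    panels: list[GenotypePanel] = []
    info: dict[str, dict] = {}
    for k in range(config.n_crosses):
        rng = np.random.default_rng(family_seqs[k])
        cross_type = "one_way" if rng.random() < config.cross_mix[0] else "three_way"
        n_parents = 2 if cross_type == "one_way" else 3
        if parent_groups is not None:
            ga, gb = parent_groups
            pa = int(rng.choice(np.asarray(ga)))
            pb = int(rng.choice(np.asarray(gb)))
            others = [i for i in range(len(founders)) if i not in (pa, pb)]
            extra = [int(rng.choice(np.asarray(others)))] if n_parents == 3 else []
            parent_idx = [pa, pb] + extra
        else:
            parent_idx = list(rng.choice(len(founders), size=n_parents, replace=False))
        f1 = make_cross([founders[i] for i in parent_idx], cross_type, gmap, rng)
        family_id = f"F{k:03d}"
        cohort, deaths = single_seed_descent(
            f1,
            config.family_size,
            config.final_generation,
            gmap,
            config.selection,
            rng,
            redraw_budget=config.redraw_budget_factor * config.family_size,
        )
        panels.append(cohort_to_panel(cohort, gmap, family_id))
        info[family_id] = {
            "cross_type": cross_type,
            "parents": parent_idx,
            "deaths": deaths,
        }
    if not panels:
        markers = gmap.marker_records()
        empty = GenotypePanel.from_parts(markers, [], np.empty((gmap.n_markers, 0)))
        return empty, {}
    return _concat_panels(panels), info


# ---------------------------------------------------------------------------
# Experiments


@dataclass
class DriftNullReport:
    """Outcome of the drift-only experiment pushed through the full screen."""

    n_families: int
    n_markers_total: int
    n_markers_screened: int
    n_candidates: int
    candidate_pairs: list[tuple[str, str]]
    max_family_r2: float
    max_pooled_r2: float
    n_pairs_defined_2plus: int
    family_r2_hist: np.ndarray
    pooled_r2_hist: np.ndarray
    hist_bins: np.ndarray
    total_attrition: int


def _screen_panel(
    pooled: GenotypePanel, analysis: AnalysisConfig, accumulator=None
) -> tuple[list, "object", dict]:
    """Run the full two-stage discovery screen on a pooled multi-family panel."""
    from . import discovery as disc

    marker_set = disc.discovery_marker_set(
        pooled, analysis.maf_min_discovery, per_family=analysis.maf_per_family
    )
    families = {
        fam: p for fam, p in pooled.split_families().items() if p.n_samples >= 2
    }
    fam_result = disc.per_family_screen(
        families,
        analysis.r2_family,
        marker_set,
        het_as_missing=analysis.ld_het_as_missing,
        accumulator=accumulator,
    )
    combined = disc.combined_screen(
        pooled, analysis.r2_combined, marker_set, het_as_missing=analysis.ld_het_as_missing
    )
    markers = {m.marker_id: m for m in pooled.markers}
    candidates = disc.select_candidates(
        fam_result,
        combined,
        markers,
        analysis.min_families,
        analysis.average_family_mode,
    )
    return candidates, fam_result, {"marker_set": marker_set, "combined": combined}


def drift_null_experiment(
    config: SimConfig | None = None,
    analysis: AnalysisConfig | None = None,
    seed: int | None = None,
) -> DriftNullReport:
    """Simulate drift-only families and apply the full candidate criteria.

    Reports the candidate count (the published comparison found none) plus the
    per-family and pooled interchromosomal r^2 distributions restricted to
    pairs polymorphic in at least two families.
    """
    from .ld_core import _r2_block, interchromosomal_mask

    if config is None:
        config = SimConfig()
    if seed is not None:
        config = SimConfig(**{**config.__dict__, "seed": seed})
    if config.selection.mode != "none":
        raise ValueError("drift_null_experiment requires selection mode 'none'")
    if analysis is None:
        analysis = AnalysisConfig()

    gmap = config.build_map()
    pooled, info = simulate_families(config, gmap)
    bins = np.linspace(0.0, 1.0, 51)
    if pooled.n_samples == 0 or config.n_crosses == 0:
        return DriftNullReport(
            0, pooled.n_markers, 0, 0, [], float("nan"), float("nan"), 0,
            np.zeros(bins.size - 1, dtype=np.int64),
            np.zeros(bins.size - 1, dtype=np.int64),
            bins, 0,
        )

    from . import discovery as disc
    from .genotype_io import subset_panel
    from .ld_core import mask_heterozygous_calls

    # pairs polymorphic (defined r^2) in >= 2 families — cheap variance pass
    marker_set = disc.discovery_marker_set(
        pooled, analysis.maf_min_discovery, per_family=analysis.maf_per_family
    )
    sub = subset_panel(pooled, marker_ids=marker_set)
    if analysis.ld_het_as_missing:
        sub = mask_heterozygous_calls(sub)
    families = {fam: p for fam, p in sub.split_families().items()}
    m = sub.n_markers
    inter = interchromosomal_mask(sub.chromosomes)
    upper = np.triu(np.ones((m, m), dtype=bool), k=1) & inter
    defined_count = np.zeros((m, m), dtype=np.int16)
    for p in families.values():
        var = np.nanvar(p.dosage, axis=1)
        poly = var > 1e-12
        defined_count += poly[:, None] & poly[None, :]
    eligible = upper & (defined_count >= 2)

    # family r^2 distribution is collected while the screen runs
    fam_hist = np.zeros(bins.size - 1, dtype=np.int64)
    max_r2 = [0.0]

    def _collect(_fam: str, r2: np.ndarray) -> None:
        vals = r2[eligible]
        vals = vals[~np.isnan(vals)]
        if vals.size:
            fam_hist[:] += np.histogram(vals, bins=bins)[0]
            max_r2[0] = max(max_r2[0], float(vals.max()))

    candidates, fam_result, _extra = _screen_panel(pooled, analysis, accumulator=_collect)
    max_family_r2 = max_r2[0]

    pooled_r2 = _r2_block(sub.dosage, sub.dosage)
    pvals = pooled_r2[eligible]
    pvals = pvals[~np.isnan(pvals)]
    pooled_hist = np.histogram(pvals, bins=bins)[0]
    max_pooled_r2 = float(pvals.max()) if pvals.size else float("nan")

    return DriftNullReport(
        n_families=len(families),
        n_markers_total=pooled.n_markers,
        n_markers_screened=len(marker_set),
        n_candidates=len(candidates),
        candidate_pairs=[(h.marker_a, h.marker_b) for h in candidates],
        max_family_r2=max_family_r2,
        max_pooled_r2=max_pooled_r2,
        n_pairs_defined_2plus=int(eligible.sum()),
        family_r2_hist=fam_hist,
        pooled_r2_hist=pooled_hist,
        hist_bins=bins,
        total_attrition=sum(d["deaths"] for d in info.values()),
    )


@dataclass
class PlantedReport:
    """End-to-end recovery outcome for a planted selection experiment."""

    planted_loci: tuple[str, ...]
    mode: str
    recovered: bool
    n_candidates: int
    candidate_pairs: list[tuple[str, str]]
    family_patterns: list
    n_opposed_pair_families: int
    validation: object
    program_share: object
    pooled_favored: tuple[str, ...]
    pooled_opposed: tuple[str, ...]
    total_attrition: int


def _default_planted_loci(gmap: GeneticMap) -> tuple[str, str]:
    """Mid-chromosome markers on two different chromosomes (1A and 4A by default)."""
    ca = 0
    cb = min(9, gmap.n_chromosomes - 1)
    if cb == ca:
        raise ValueError("planted experiment needs at least 2 chromosomes")
    ma = gmap.marker_ids[ca][len(gmap.marker_ids[ca]) // 2]
    mb = gmap.marker_ids[cb][len(gmap.marker_ids[cb]) // 2]
    return ma, mb


def planted_epistasis_experiment(
    config: SimConfig | None = None,
    analysis: AnalysisConfig | None = None,
    seed: int | None = None,
) -> PlantedReport:
    """Plant two-locus (or three-locus) selection and run discovery +
    combination analysis end to end.

    For epistatic mode, half the founder pool is fixed for one favored
    combination and half for its complement; every cross pairs parents from
    opposite groups, so all families segregate at the planted loci. For
    additive mode the same construction is used but selection favors one
    allele at the first planted locus only — the control that the pipeline
    must reject or fail to nominate.
    """
    if config is None:
        config = SimConfig(
            n_crosses=10,
            family_size=20,
            cross_mix=(1.0, 0.0),
            selection=SelectionModel(mode="epistatic", s=1.0, h=0.0),
        )
    if seed is not None:
        config = SimConfig(**{**config.__dict__, "seed": seed})
    if analysis is None:
        analysis = AnalysisConfig()
    if config.selection.mode == "none":
        raise ValueError("planted experiment requires a selection model")

    gmap = config.build_map()
    model = config.selection
    if not model.loci:
        loci = _default_planted_loci(gmap)
        if model.mode == "epistatic":
            model = SelectionModel(
                mode="epistatic",
                loci=loci,
                favored_combinations=((0,) * len(loci), (1,) * len(loci)),
                s=model.s,
                h=model.h,
            )
        else:
            model = SelectionModel(
                mode="additive",
                loci=(loci[0],),
                favored_allele=model.favored_allele,
                s=model.s,
                h=model.h,
            )
        planted_pair = loci
    else:
        planted_pair = model.loci if model.mode == "epistatic" else (
            model.loci[0],
            _default_planted_loci(gmap)[1],
        )
    config = SimConfig(**{**config.__dict__, "selection": model})

    # founder pool fixed for complementary combinations at the planted loci
    root = np.random.SeedSequence(config.seed)
    founder_seq = root.spawn(1)[0]
    founders = synth_founders(config, gmap, np.random.default_rng(founder_seq))
    locus_idx = [gmap.locus(mid) for mid in planted_pair]
    group_a, group_b = [], []
    for i, founder in enumerate(founders):
        target = i % 2
        for ci, mi in locus_idx:
            founder.haplotypes[ci][:, mi] = target
        (group_a if target == 0 else group_b).append(i)

    pooled, info = simulate_families(
        config, gmap, founders=founders, parent_groups=(group_a, group_b)
    )

    candidates, fam_result, _ = _screen_panel(pooled, analysis)
    candidate_pairs = [(h.marker_a, h.marker_b) for h in candidates]
    key = tuple(sorted(planted_pair[:2]))
    recovered = any(tuple(sorted(pair)) == key for pair in candidate_pairs)

    from .combination_analysis import (
        classify_family_pattern,
        combination_table,
        favored_and_opposed,
        program_share_test,
        validation_verdict,
    )

    table_loci = list(planted_pair[:2]) if model.mode == "additive" else list(model.loci)
    pooled_table = combination_table(pooled, table_loci, group_id="pooled")
    favored, opposed = favored_and_opposed(pooled_table)
    patterns = []
    for fam in pooled.family_ids():
        sub_ids = [s.sample_id for s in pooled.samples if s.family_id == fam]
        table = combination_table(pooled, table_loci, group_id=fam, sample_ids=sub_ids)
        patterns.append(classify_family_pattern(table, analysis, favored, opposed))
    verdict = validation_verdict("planted", patterns)
    share = program_share_test(pooled_table, analysis.opposite_min_share, favored, opposed)

    return PlantedReport(
        planted_loci=tuple(table_loci),
        mode=model.mode,
        recovered=recovered,
        n_candidates=len(candidates),
        candidate_pairs=candidate_pairs,
        family_patterns=patterns,
        n_opposed_pair_families=sum(1 for p in patterns if p.label == "opposed_pair"),
        validation=verdict,
        program_share=share,
        pooled_favored=favored,
        pooled_opposed=opposed,
        total_attrition=sum(d["deaths"] for d in info.values()),
    )
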