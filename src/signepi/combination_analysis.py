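"""Allelic-combination frequency tables and the falsification rules.

Sign epistasis and additive selection leave different fingerprints on the
two-locus (or three-locus) homozygous allele-combination counts of inbred
families. Under sign epistasis the "favored" combination and its allele-wise
complement (the "opposed" combination) both persist at high frequency, while
the remaining "off" combinations are purged; under additive selection a single
combination dominates and its complement decays below a detectable share.

This module builds combination tables per sample group, classifies families
against those expectations, and applies the validation falsification rules:
any segregating family whose most frequent combination is an off-combination
rejects the interaction; an opposed-combination share below 10% of the pooled
breeding program rejects it; an interaction resting on a single-marker region
is rejected as a likely alignment artifact.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .discovery import Interaction
from .genotype_io import STAGES, GenotypePanel, subset_panel

__all__ = [
    "CombinationTable",
    "PatternCall",
    "Verdict",
    "PATTERN_LABELS",
    "combination_table",
    "favored_and_opposed",
    "classify_family_pattern",
    "validation_verdict",
    "program_share_test",
    "single_marker_flag",
    "stage_frequency_track",
    "independence_expectation",
]

PATTERN_LABELS = (
    "opposed_pair",
    "predominant_with_opposed",
    "single_dominant",
    "off_fixed_parental",
    "off_dominant_segregating",
    "het_inconclusive",
)


@dataclass
class CombinationTable:
    """Counts of the 2^k homozygous allele combinations at k interacting loci.

    ``loci`` holds (marker_id, ref_allele, alt_allele) per locus; keys of
    ``homo_counts`` are allele tuples. Samples heterozygous at any locus go to
    ``het_count``; samples missing or imputed at any locus to ``missing_count``.
    """

    loci: list[tuple[str, str, str]]
    group_id: str
    homo_counts: dict[tuple[str, ...], int]
    het_count: int
    missing_count: int
    total: int

    def __post_init__(self) -> None:
        if sum(self.homo_counts.values()) + self.het_count + self.missing_count != self.total:
            raise ValueError("combination counts do not conserve the sample total")
        if any(c < 0 for c in self.homo_counts.values()) or min(
            self.het_count, self.missing_count, self.total
        ) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def k(self) -> int:
        return len(self.loci)

    @property
    def n_called(self) -> int:
        return self.total - self.missing_count

    def share(self, combo: tuple[str, ...]) -> float:
        """Share of a homozygous combination among called samples."""
        if self.n_called == 0:
            return float("nan")
        return self.homo_counts.get(combo, 0) / self.n_called

    @property
    def het_share(self) -> float:
        if self.n_called == 0:
            return float("nan")
        return self.het_count / self.n_called

    def complement(self, combo: tuple[str, ...]) -> tuple[str, ...]:
        """Swap each locus's allele for its alternative."""
        out = []
        for allele, (_, ref, alt) in zip(combo, self.loci):
            if allele == ref:
                out.append(alt)
            elif allele == alt:
                out.append(ref)
            else:
                raise ValueError(f"allele {allele!r} not in locus alleles ({ref}/{alt})")
        return tuple(out)


@dataclass(frozen=True)
class PatternCall:
    """The allele-frequency pattern of one family at a candidate interaction."""

    group_id: str
    label: str
    favored: tuple[str, ...]
    opposed: tuple[str, ...]
    off_share: float


@dataclass
class Verdict:
    """Outcome of one falsification rule (or their combination) for an interaction."""

    interaction_id: str
    status: str  # retained / rejected / flagged
    reason: str = "none"
    evidence: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.status == "rejected" and self.reason == "none":
            raise ValueError("a rejection requires a reason")


# ---------------------------------------------------------------------------
# Table construction


def combination_table(
    panel: GenotypePanel,
    loci: Sequence[str],
    group_id: str = "all",
    sample_ids: Sequence[str] | None = None,
) -> CombinationTable:
    """Count homozygous allele combinations at k loci for one sample group.

    Imputed entries are treated as missing: a combination class requires a
    called genotype, and a fractional mean-imputed dosage has none.
    """
    if not 2 <= len(loci) <= 3:
        raise ValueError("combination tables support k = 2 or 3 loci")
    idx = [panel.marker_index(m) for m in loci]
    recs = [panel.markers[i] for i in idx]
    if len({r.chromosome for r in recs}) != len(recs):
        raise ValueError("combination loci must lie on distinct chromosomes")
    if sample_ids is not None:
        cols = [panel.sample_ids.index(s) for s in sample_ids]
    else:
        cols = list(range(panel.n_samples))

    alleles = [(r.marker_id, r.ref_allele, r.alt_allele) for r in recs]
    homo_counts: dict[tuple[str, ...], int] = {
        combo: 0
        for combo in itertools.product(*[(ref, alt) for _, ref, alt in alleles])
    }
    het = 0
    missing = 0
    D = panel.dosage[np.ix_(idx, cols)]
    M = panel.imputed_mask[np.ix_(idx, cols)]
    for j in range(len(cols)):
        d = D[:, j]
        if np.any(np.isnan(d)) or np.any(M[:, j]) or np.any((d != 0) & (d != 1) & (d != 2)):
            missing += 1
        elif np.any(d == 1):
            het += 1
        else:
            combo = tuple(
                alt if d[l] == 2 else ref for l, (_, ref, alt) in enumerate(alleles)
            )
            homo_counts[combo] += 1
    return CombinationTable(
        loci=alleles,
        group_id=group_id,
        homo_counts=homo_counts,
        het_count=het,
        missing_count=missing,
        total=len(cols),
    )


def favored_and_opposed(table: CombinationTable) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Most frequent homozygous combination and its allele-wise complement.

    Ties go to the lexicographically smallest allele tuple, so the favored/
    opposed labels are deterministic for identical inputs.
    """
    if sum(table.homo_counts.values()) == 0:
        raise ValueError("no homozygous calls: favored combination undefined")
    favored = min(
        table.homo_counts, key=lambda c: (-table.homo_counts[c], c)
    )
    return favored, table.complement(favored)


# ---------------------------------------------------------------------------
# Pattern classification


def classify_family_pattern(
    table: CombinationTable,
    config: AnalysisConfig | None = None,
    favored: tuple[str, ...] | None = None,
    opposed: tuple[str, ...] | None = None,
) -> PatternCall:
    """Label one family's combination table against the selection expectations.

    ``favored``/``opposed`` are the panel-level reference combinations; when
    omitted they are taken from the family table itself (in which case the
    off-dominant labels cannot trigger). Rules, in order:

    1. heterozygote share above ``het_inconclusive_share`` -> het_inconclusive;
    2. an off-combination is most frequent and the family is fixed for it
       (share >= ``fixation_threshold``) -> off_fixed_parental (the parental-
       fixation case, tolerated downstream);
    3. an off-combination is most frequent in a segregating family ->
       off_dominant_segregating (grounds for rejection downstream);
    4. favored and opposed both at share >= 0.10 -> opposed_pair (the
       sign-epistasis expectation);
    5. otherwise single_dominant (top combination at fixation share) or
       predominant_with_opposed.
    """
    if config is None:
        config = AnalysisConfig()
    if favored is None or opposed is None:
        favored, opposed = favored_and_opposed(table)
    off_combos = [
        c for c in table.homo_counts if c != favored and c != opposed
    ]
    off_share = sum(table.share(c) for c in off_combos) if table.n_called else float("nan")

    def call(label: str) -> PatternCall:
        return PatternCall(
            group_id=table.group_id,
            label=label,
            favored=favored,
            opposed=opposed,
            off_share=float(off_share),
        )

    if table.n_called == 0 or table.het_share > config.het_inconclusive_share:
        return call("het_inconclusive")

    n_homo = sum(table.homo_counts.values())
    if n_homo > 0:
        top = min(table.homo_counts, key=lambda c: (-table.homo_counts[c], c))
        if top in off_combos:
            if table.share(top) >= config.fixation_threshold:
                return call("off_fixed_parental")
            return call("off_dominant_segregating")
    if table.share(favored) >= 0.10 and table.share(opposed) >= 0.10:
        return call("opposed_pair")
    top_share = max(table.share(favored), table.share(opposed))
    if top_share >= config.fixation_threshold:
        return call("single_dominant")
    return call("predominant_with_opposed")


# ---------------------------------------------------------------------------
# Falsification rules


def validation_verdict(
    interaction_id: str, family_patterns: Sequence[PatternCall]
) -> Verdict:
    """Independent-family rule: any segregating family dominated by an
    off-combination rejects the interaction; heterozygote-inconclusive families
    (absent a rejection) flag it; parental off-fixation is tolerated."""
    if not family_patterns:
        raise ValueError("validation verdict requires at least one family pattern")
    labels = [p.label for p in family_patterns]
    evidence = {
        "n_families": len(labels),
        "label_counts": {lab: labels.count(lab) for lab in set(labels)},
    }
    if "off_dominant_segregating" in labels:
        return Verdict(interaction_id, "rejected", "off_most_frequent_in_validation", evidence)
    if "het_inconclusive" in labels:
        return Verdict(interaction_id, "flagged", "none", evidence)
    return Verdict(interaction_id, "retained", "none", evidence)


def program_share_test(
    table: CombinationTable,
    opposite_min_share: float = 0.10,
    favored: tuple[str, ...] | None = None,
    opposed: tuple[str, ...] | None = None,
) -> Verdict:
    """Breeding-program rule: reject when the opposed combination holds less
    than ``opposite_min_share`` of called combinations (strict, as printed)."""
    if favored is None or opposed is None:
        favored, opposed = favored_and_opposed(table)
    share = table.share(opposed)
    evidence = {"opposed_share": float(share), "favored": favored, "opposed": opposed}
    if np.isnan(share) or share < opposite_min_share:
        return Verdict(table.group_id, "rejected", "opposite_share_below_min", evidence)
    return Verdict(table.group_id, "retained", "none", evidence)


def single_marker_flag(interaction: Interaction) -> Verdict:
    """Reject interactions where any region rests on a single marker — a lone
    GBS marker can owe its LD to an alignment error rather than biology."""
    singles = [r.region_id for r in interaction.regions if r.n_markers == 1]
    evidence = {"single_marker_regions": singles}
    if singles:
        return Verdict(interaction.interaction_id, "rejected", "single_marker_region", evidence)
    return Verdict(interaction.interaction_id, "retained", "none", evidence)


# ---------------------------------------------------------------------------
# Stage tracking and expectation


def stage_frequency_track(
    panel: GenotypePanel,
    loci: Sequence[str],
    favored: tuple[str, ...] | None = None,
    opposed: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Combination shares per breeding stage, in pipeline order IPSR..EYN.

    Stages absent from the panel are skipped; a stage with zero informative
    samples is emitted with zero total. Columns: per-combination shares plus
    heterozygote share and counts.
    """
    stages_present = [s for s in STAGES if any(x.stage == s for x in panel.samples)]
    if favored is None or opposed is None:
        pooled = combination_table(panel, loci, group_id="pooled")
        favored, opposed = favored_and_opposed(pooled)
    rows = []
    for stage in stages_present:
        sub_ids = [s.sample_id for s in panel.samples if s.stage == stage]
        table = combination_table(panel, loci, group_id=stage, sample_ids=sub_ids)
        row: dict[str, object] = {"stage": stage, "total": table.total}
        row["favored_share"] = table.share(favored)
        row["opposed_share"] = table.share(opposed)
        off = [c for c in table.homo_counts if c not in (favored, opposed)]
        row["off_share"] = (
            float(sum(table.share(c) for c in off)) if table.n_called else float("nan")
        )
        row["het_share"] = table.het_share
        for combo in sorted(table.homo_counts):
            row["share_" + "/".join(combo)] = table.share(combo)
        rows.append(row)
    return pd.DataFrame(rows)


def independence_expectation(table: CombinationTable) -> dict[tuple[str, ...], float]:
    """Expected homozygous-combination shares under linkage equilibrium.

    Each combination's expected share is the product of its per-locus marginal
    homozygote shares (renormalized over the homozygous classes), i.e. the
    no-association expectation that preserves the observed inbreeding; shares
    sum to 1 over the 2^k classes. Literal Hardy-Weinberg proportions would be
    wrong for selfed lines, which are far from panmixia.
    """
    n_homo = sum(table.homo_counts.values())
    if n_homo == 0:
        raise ValueError("no homozygous calls: expectation undefined")
    marginals: list[dict[str, float]] = []
    for l, (marker_id, ref, alt) in enumerate(table.loci):
        m = {ref: 0.0, alt: 0.0}
        for combo, count in table.homo_counts.items():
            m[combo[l]] += count
        total = m[ref] + m[alt]
        if total == 0:
            raise ValueError(f"locus {marker_id}: no homozygous calls")
        marginals.append({a: c / total for a, c in m.items()})
    return {
        combo: float(np.prod([marginals[l][a] for l, a in enumerate(combo)]))
        for combo in table.homo_counts
    }
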