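"""Two-stage candidate screen for interchromosomal selection signatures.

The screen controls the two confounders of an interchromosomal LD scan in
breeding germplasm separately:

* population structure — LD is computed inside each biparental family
  individually (r^2 > ``r2_family`` retained);
* genetic drift — the same pairs must also hold on the pooled families
  (r^2 > ``r2_combined``), where family-private associations with random
  phase cancel out.

Pairs passing both stages in at least ``min_families`` families become
candidates; their markers are grouped into physical regions, and region
triangles across three chromosomes are reported as 3-way candidates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from sklearn.decomposition import PCA

from .config import AnalysisConfig
from .genotype_io import GenotypePanel, MarkerRecord, chromosome_sort_key, marker_stats, subset_panel
from .ld_core import _r2_block, interchromosomal_mask, r2_pairs

__all__ = [
    "PairHit",
    "Region",
    "Interaction",
    "FamilyScreenResult",
    "pca_outlier_filter",
    "discovery_marker_set",
    "per_family_screen",
    "combined_screen",
    "select_candidates",
    "group_regions",
    "detect_multiway",
]

REJECTION_REASONS = (
    "none",
    "off_most_frequent_in_validation",
    "opposite_share_below_min",
    "single_marker_region",
    "drift_suspected",
)


@dataclass
class PairHit:
    """An interchromosomal marker pair passing both screening stages."""

    marker_a: str
    marker_b: str
    family_r2: dict[str, float]  # NaN where the pair is monomorphic in a family
    n_families_passing: int
    combined_r2: float


@dataclass
class Region:
    """A physical cluster of candidate markers on one chromosome."""

    region_id: str
    chromosome: str
    start: int
    end: int
    member_markers: list[str]

    @property
    def n_markers(self) -> int:
        return len(self.member_markers)


@dataclass
class Interaction:
    """k regions on distinct chromosomes connected by candidate marker pairs."""

    interaction_id: str
    regions: tuple[Region, ...]
    member_pairs: list[PairHit]
    status: str = "candidate"
    rejection_reason: str = "none"

    @property
    def k(self) -> int:
        return len(self.regions)


@dataclass
class FamilyScreenResult:
    """Per-family r^2 of every pair passing the family stage in >= 1 family."""

    threshold: float
    pairs: dict[tuple[str, str], dict[str, float]] = field(default_factory=dict)

    def n_families_passing(self, pair: tuple[str, str]) -> int:
        vals = self.pairs[pair]
        return int(sum(1 for v in vals.values() if not np.isnan(v) and v > self.threshold))


# ---------------------------------------------------------------------------
# Sample QC


def pca_outlier_filter(
    family_panel: GenotypePanel,
    outlier_sd: float = 3.0,
    max_removed_frac: float = 0.20,
) -> tuple[list[str], list[str]]:
    """Flag family members far from the family centroid on PC1-PC2.

    Samples are projected onto the first two principal components of the
    centered dosage matrix; those whose Euclidean distance from the family
    centroid exceeds ``outlier_sd`` times the root-mean-square distance are
    removed, capped at ``max_removed_frac`` of the family (worst first).
    Families smaller than 5 are returned unfiltered with a warning.
    """
    ids = family_panel.sample_ids
    n = len(ids)
    if n < 5:
        warnings.warn(
            f"family of {n} samples too small for PCA outlier QC; kept unfiltered",
            stacklevel=2,
        )
        return list(ids), []
    X = family_panel.dosage.T.copy()  # samples x markers
    col_means = np.nanmean(family_panel.dosage, axis=1)
    nan_rows, nan_cols = np.nonzero(np.isnan(X))
    X[nan_rows, nan_cols] = col_means[nan_cols]
    n_comp = min(2, n - 1, X.shape[1])
    scores = PCA(n_components=n_comp, svd_solver="full").fit_transform(X)
    centroid = scores.mean(axis=0)
    d = np.linalg.norm(scores - centroid, axis=1)
    rms = float(np.sqrt(np.mean(d**2)))
    if rms == 0.0:
        return list(ids), []
    outliers = np.flatnonzero(d > outlier_sd * rms)
    cap = int(np.floor(max_removed_frac * n))
    if outliers.size > cap:
        outliers = outliers[np.argsort(d[outliers])[::-1][:cap]]
    removed = sorted((ids[i] for i in outliers), key=ids.index)
    kept = [s for s in ids if s not in set(removed)]
    return kept, removed


# ---------------------------------------------------------------------------
# Screens


def discovery_marker_set(
    pooled_panel: GenotypePanel, maf_min: float, per_family: bool = False
) -> list[str]:
    """Markers entering the discovery screen: MAF > ``maf_min`` (strict), placed
    on a chromosome. Evaluated on the pooled panel by default so every family
    screens one shared marker universe; ``per_family`` instead requires the
    threshold within every family."""
    stats = marker_stats(pooled_panel)
    maf = stats["maf"].to_numpy()
    keep = (maf > maf_min) & ~np.isnan(maf) & (pooled_panel.chromosomes != "UN")
    if per_family:
        for fam_panel in pooled_panel.split_families().values():
            fam_maf = marker_stats(fam_panel)["maf"].to_numpy()
            keep &= (fam_maf > maf_min) & ~np.isnan(fam_maf)
    return [m for m, k in zip(pooled_panel.marker_ids, keep) if k]


def _ordered_pair(ma: MarkerRecord, mb: MarkerRecord) -> tuple[MarkerRecord, MarkerRecord]:
    ka = (chromosome_sort_key(ma.chromosome), ma.position, ma.marker_id)
    kb = (chromosome_sort_key(mb.chromosome), mb.position, mb.marker_id)
    return (ma, mb) if ka <= kb else (mb, ma)


def per_family_screen(
    families: Mapping[str, GenotypePanel],
    r2_family: float = 0.9,
    marker_ids: Sequence[str] | None = None,
    het_as_missing: bool = True,
    accumulator=None,
) -> FamilyScreenResult:
    """Interchromosomal LD inside each family; pairs with r^2 > ``r2_family``
    in at least one family are retained with their full per-family r^2 profile.

    Families where either marker is monomorphic contribute NaN (undefined), not
    zero — they neither pass nor veto a pair. Heterozygous calls are excluded
    from the correlations by default (mostly-inbred panels; see
    :func:`signepi.ld_core.mask_heterozygous_calls`).

    ``accumulator(family_id, r2)``, when given, is called once per family with
    the full r^2 matrix (marker order of the screen), so callers can collect
    LD distributions without recomputing the correlations.
    """
    if len(families) < 2:
        raise ValueError("per-family screen needs at least 2 families")
    first = next(iter(families.values()))
    ids = list(marker_ids) if marker_ids is not None else first.marker_ids
    sub_panels = {
        fam: subset_panel(p, marker_ids=ids) for fam, p in families.items()
    }
    if het_as_missing:
        from .ld_core import mask_heterozygous_calls

        sub_panels = {fam: mask_heterozygous_calls(p) for fam, p in sub_panels.items()}
    chroms = next(iter(sub_panels.values())).chromosomes
    inter = interchromosomal_mask(chroms)
    upper = np.triu(np.ones((len(ids), len(ids)), dtype=bool), k=1)
    passing: set[tuple[int, int]] = set()
    for fam, p in sub_panels.items():
        if p.marker_ids != ids:
            raise ValueError(f"family {fam} does not share the screening marker set")
        r2 = _r2_block(p.dosage, p.dosage)
        if accumulator is not None:
            accumulator(fam, r2)
        ok = np.zeros_like(r2, dtype=bool)
        with np.errstate(invalid="ignore"):
            np.greater(r2, r2_family, out=ok, where=~np.isnan(r2))
        ok &= inter & upper
        passing.update(zip(*np.nonzero(ok)))

    result = FamilyScreenResult(threshold=r2_family)
    if not passing:
        return result
    pair_idx = sorted(passing)
    ia = np.array([i for i, _ in pair_idx])
    ib = np.array([j for _, j in pair_idx])
    values_by_family = {
        fam: r2_pairs(p.dosage, ia, ib) for fam, p in sub_panels.items()
    }
    for k, (i, j) in enumerate(pair_idx):
        result.pairs[(ids[i], ids[j])] = {
            fam: float(values_by_family[fam][k]) for fam in sub_panels
        }
    return result


def combined_screen(
    pooled_panel: GenotypePanel,
    r2_combined: float = 0.8,
    marker_ids: Sequence[str] | None = None,
    block_size: int = 512,
    het_as_missing: bool = True,
) -> dict[tuple[str, str], float]:
    """Interchromosomal pairs with pooled r^2 > ``r2_combined`` (strict)."""
    ids = list(marker_ids) if marker_ids is not None else pooled_panel.marker_ids
    sub = subset_panel(pooled_panel, marker_ids=ids)
    if sub.marker_ids != ids:
        ids = sub.marker_ids  # subsetting preserves panel (sorted) order
    if het_as_missing:
        from .ld_core import mask_heterozygous_calls

        sub = mask_heterozygous_calls(sub)
    chroms = sub.chromosomes
    out: dict[tuple[str, str], float] = {}
    m = len(ids)
    for start in range(0, m, block_size):
        stop = min(start + block_size, m)
        r2 = _r2_block(sub.dosage[start:stop], sub.dosage)
        ok = np.zeros_like(r2, dtype=bool)
        with np.errstate(invalid="ignore"):
            np.greater(r2, r2_combined, out=ok, where=~np.isnan(r2))
        ok &= chroms[start:stop, None] != chroms[None, :]
        ok &= (chroms[start:stop] != "UN")[:, None] & (chroms != "UN")[None, :]
        ok &= np.arange(start, stop)[:, None] < np.arange(m)[None, :]
        for i, j in zip(*np.nonzero(ok)):
            out[(ids[start + i], ids[j])] = float(r2[i, j])
    return out


def select_candidates(
    per_family: FamilyScreenResult,
    combined: Mapping[tuple[str, str], float],
    markers: Mapping[str, MarkerRecord],
    min_families: int = 2,
    average_family_mode: bool = False,
) -> list[PairHit]:
    """Intersect the two screening stages into the candidate pair list.

    A pair is a candidate when it passed the family stage in at least
    ``min_families`` families AND the combined stage. ``average_family_mode``
    instead requires the mean defined per-family r^2 to exceed the family
    threshold (with >= ``min_families`` families segregating).
    """
    hits: list[PairHit] = []
    for pair, fam_r2 in per_family.pairs.items():
        if pair not in combined:
            continue
        defined = [v for v in fam_r2.values() if not np.isnan(v)]
        n_pass = per_family.n_families_passing(pair)
        if average_family_mode:
            ok = len(defined) >= min_families and float(np.mean(defined)) > per_family.threshold
        else:
            ok = n_pass >= min_families
        if not ok:
            continue
        ma, mb = _ordered_pair(markers[pair[0]], markers[pair[1]])
        hits.append(
            PairHit(
                marker_a=ma.marker_id,
                marker_b=mb.marker_id,
                family_r2=dict(fam_r2),
                n_families_passing=n_pass,
                combined_r2=combined[pair],
            )
        )
    hits.sort(
        key=lambda h: (
            -h.combined_r2,
            chromosome_sort_key(markers[h.marker_a].chromosome),
            markers[h.marker_a].position,
            h.marker_a,
        )
    )
    return hits


# ---------------------------------------------------------------------------
# Region grouping and multi-way assembly


def group_regions(
    hits: Sequence[PairHit],
    markers: Mapping[str, MarkerRecord],
    region_gap_bp: int = 10_000_000,
) -> tuple[list[Region], list[Interaction]]:
    """Cluster hit markers into physical regions and hits into interactions.

    Per chromosome, markers appearing in any hit are clustered by single
    linkage with an inter-marker gap of at most ``region_gap_bp``. Each
    interaction is a pair of regions connected by >= 1 hit; every hit belongs
    to exactly one interaction.
    """
    if not hits:
        raise ValueError("group_regions requires a non-empty hit list")
    by_chrom: dict[str, set[str]] = {}
    for h in hits:
        for mid in (h.marker_a, h.marker_b):
            by_chrom.setdefault(markers[mid].chromosome, set()).add(mid)

    regions: list[Region] = []
    region_of: dict[str, Region] = {}
    for chrom in sorted(by_chrom, key=chromosome_sort_key):
        mids = sorted(by_chrom[chrom], key=lambda m: (markers[m].position, m))
        clusters: list[list[str]] = [[mids[0]]]
        for mid in mids[1:]:
            if markers[mid].position - markers[clusters[-1][-1]].position <= region_gap_bp:
                clusters[-1].append(mid)
            else:
                clusters.append([mid])
        for k, members in enumerate(clusters, start=1):
            region = Region(
                region_id=f"{chrom}:{k}",
                chromosome=chrom,
                start=markers[members[0]].position,
                end=markers[members[-1]].position,
                member_markers=members,
            )
            regions.append(region)
            for mid in members:
                region_of[mid] = region

    grouped: dict[tuple[str, str], list[PairHit]] = {}
    for h in hits:
        ra, rb = region_of[h.marker_a], region_of[h.marker_b]
        key = tuple(
            sorted(
                (ra.region_id, rb.region_id),
                key=lambda rid: (
                    chromosome_sort_key(rid.split(":")[0]),
                    int(rid.split(":")[1]),
                ),
            )
        )
        grouped.setdefault(key, []).append(h)

    region_by_id = {r.region_id: r for r in regions}
    interactions = [
        Interaction(
            interaction_id=f"{key[0]}x{key[1]}",
            regions=(region_by_id[key[0]], region_by_id[key[1]]),
            member_pairs=members,
        )
        for key, members in sorted(grouped.items())
    ]
    return regions, interactions


def detect_multiway(interactions: Sequence[Interaction]) -> list[Interaction]:
    """Append k=3 candidates: region triangles spanning three distinct
    chromosomes in the pairwise-interaction graph (pairwise components kept)."""
    pairwise = [ia for ia in interactions if ia.k == 2]
    graph = nx.Graph()
    region_by_id: dict[str, Region] = {}
    edge_pairs: dict[tuple[str, str], list[PairHit]] = {}
    for ia in pairwise:
        ra, rb = ia.regions
        region_by_id[ra.region_id] = ra
        region_by_id[rb.region_id] = rb
        graph.add_edge(ra.region_id, rb.region_id)
        edge_pairs[tuple(sorted((ra.region_id, rb.region_id)))] = ia.member_pairs

    out = list(interactions)
    triangles = {
        tuple(sorted(c)) for c in nx.enumerate_all_cliques(graph) if len(c) == 3
    }
    for tri in sorted(triangles):
        regs = tuple(
            sorted(
                [region_by_id[rid] for rid in tri],
                key=lambda r: (chromosome_sort_key(r.chromosome), r.start),
            )
        )
        if len({r.chromosome for r in regs}) != 3:
            continue
        members: list[PairHit] = []
        for a in range(3):
            for b in range(a + 1, 3):
                members.extend(edge_pairs[tuple(sorted((regs[a].region_id, regs[b].region_id)))])
        out.append(
            Interaction(
                interaction_id="x".join(r.region_id for r in regs),
                regions=regs,
                member_pairs=members,
            )
        )
    return out
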