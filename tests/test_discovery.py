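"""Two-stage screen, PCA outlier QC, region grouping, multi-way assembly."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from signepi.discovery import (
    Interaction,
    PairHit,
    Region,
    combined_screen,
    detect_multiway,
    group_regions,
    pca_outlier_filter,
    per_family_screen,
    select_candidates,
)
from signepi.genotype_io import MarkerRecord, chromosome_sort_key
from signepi.ld_core import pairwise_r2
from tests.conftest import build_panel


def _random_family_fixture(rng, n_markers=12, n_families=3, fam_size=10, correlated=2):
    """Pooled panel of inbred families; the first `correlated` interchromosomal
    markers are duplicated columns inside every family (planted strong LD)."""
    chroms = [f"{1 + i % 4}{'AB'[i % 2]}" for i in range(n_markers)]
    panels = []
    for f in range(n_families):
        d = rng.choice([0.0, 2.0], size=(n_markers, fam_size))
        if correlated:
            # markers 0 and 1 are on different chromosomes by construction
            d[1] = d[0]
        panels.append(d)
    dosage = np.concatenate(panels, axis=1)
    families = [f"F{f}" for f in range(n_families) for _ in range(fam_size)]
    return build_panel(chroms, dosage, families=families), chroms


def _oracle_candidates(panel, r2_family, r2_combined, min_families):
    """Exhaustive enumeration of the two-stage rule via scalar pairwise_r2."""
    fams = panel.split_families()
    ids = panel.marker_ids
    chroms = {m.marker_id: m.chromosome for m in panel.markers}
    out = set()
    for a, b in itertools.combinations(range(len(ids)), 2):
        if chroms[ids[a]] == chroms[ids[b]]:
            continue
        n_pass = 0
        for p in fams.values():
            r2 = pairwise_r2(p.dosage[a], p.dosage[b])
            if not math.isnan(r2) and r2 > r2_family:
                n_pass += 1
        pooled = pairwise_r2(panel.dosage[a], panel.dosage[b])
        if n_pass >= min_families and not math.isnan(pooled) and pooled > r2_combined:
            out.add(tuple(sorted((ids[a], ids[b]))))
    return out


def test_two_stage_screen_matches_exhaustive_oracle(rng):
    panel, _ = _random_family_fixture(rng)
    fams = panel.split_families()
    fam_result = per_family_screen(fams, 0.9, panel.marker_ids)
    combined = combined_screen(panel, 0.8, panel.marker_ids)
    markers = {m.marker_id: m for m in panel.markers}
    hits = select_candidates(fam_result, combined, markers, min_families=2)
    got = {tuple(sorted((h.marker_a, h.marker_b))) for h in hits}
    want = _oracle_candidates(panel, 0.9, 0.8, 2)
    assert got == want
    assert want  # the planted duplicated pair must be present
    for h in hits:
        assert markers[h.marker_a].chromosome != markers[h.marker_b].chromosome
        assert h.n_families_passing >= 2


def test_opposite_phase_families_cancel_in_pooled_screen():
    """Perfect within-family LD with opposite phase across balanced families
    pools to r^2 ~ 0 — the drift-elimination logic of the combined stage."""
    x = np.array([0.0, 2.0] * 5)
    fam1 = np.vstack([x, x])          # coupling phase
    fam2 = np.vstack([x, 2.0 - x])    # repulsion phase
    dosage = np.concatenate([fam1, fam2], axis=1)
    panel = build_panel(["1A", "4A"], dosage, families=["F1"] * 10 + ["F2"] * 10)
    fams = panel.split_families()
    fam_result = per_family_screen(fams, 0.9)
    assert fam_result.n_families_passing(("m0", "m1")) == 2
    combined = combined_screen(panel, 0.8)
    assert ("m0", "m1") not in combined
    pooled = pairwise_r2(panel.dosage[0], panel.dosage[1])
    assert pooled == pytest.approx(0.0, abs=1e-12)
    markers = {m.marker_id: m for m in panel.markers}
    assert select_candidates(fam_result, combined, markers, 2) == []
    # same phase in both families -> pooled r^2 = 1 -> selected
    panel2 = build_panel(
        ["1A", "4A"], np.concatenate([fam1, fam1], axis=1),
        families=["F1"] * 10 + ["F2"] * 10,
    )
    fams2 = panel2.split_families()
    hits = select_candidates(
        per_family_screen(fams2, 0.9), combined_screen(panel2, 0.8),
        {m.marker_id: m for m in panel2.markers}, 2,
    )
    assert [(h.marker_a, h.marker_b) for h in hits] == [("m0", "m1")]
    assert hits[0].combined_r2 == pytest.approx(1.0)


def test_combined_screen_threshold_is_strict():
    """A pooled r^2 exactly at the threshold is excluded (strict '>')."""
    x = np.array([0.0, 2.0, 0.0, 2.0, 0.0, 2.0, 2.0, 0.0])
    y = np.array([0.0, 2.0, 0.0, 2.0, 0.0, 2.0, 0.0, 2.0])
    panel = build_panel(["1A", "4A"], np.vstack([x, y]))
    r2 = pairwise_r2(x, y)
    assert ("m0", "m1") in combined_screen(panel, r2 - 1e-9)
    assert ("m0", "m1") not in combined_screen(panel, r2)


def test_monomorphic_family_contributes_undefined(rng):
    x = np.array([0.0, 2.0] * 4)
    fam = np.vstack([x, x])
    mono = np.vstack([np.zeros(8), rng.choice([0.0, 2.0], 8)])
    dosage = np.concatenate([fam, fam, mono], axis=1)
    panel = build_panel(
        ["1A", "4A"], dosage, families=["F1"] * 8 + ["F2"] * 8 + ["F3"] * 8
    )
    result = per_family_screen(panel.split_families(), 0.9)
    vals = result.pairs[("m0", "m1")]
    assert math.isnan(vals["F3"])
    assert result.n_families_passing(("m0", "m1")) == 2


def test_pca_outlier_filter():
    """A simulated identical-ancestry family survives PCA QC intact; one
    sample substituted from an unrelated cross is exactly the one removed."""
    from signepi.breeding_sim import (
        SelectionModel,
        SimConfig,
        default_wheat_map,
        make_cross,
        self_to_generation,
        synth_founders,
    )

    gmap = default_wheat_map(n_markers_per_chrom=30, n_chromosomes=7)
    sim_rng = np.random.default_rng(0)
    cfg = SimConfig(n_founders=10, n_markers_per_chrom=30, n_chromosomes=7)
    founders = synth_founders(cfg, gmap, sim_rng)
    f1 = make_cross(founders[:2], "one_way", gmap, sim_rng)
    panel = self_to_generation(f1, 20, 5, gmap, SelectionModel(), sim_rng, "fam")
    kept, removed = pca_outlier_filter(panel, outlier_sd=3.0)
    assert removed == []
    # line from an unrelated cross out of an independent founder pool
    other_rng = np.random.default_rng(1000)
    founders2 = synth_founders(cfg, gmap, other_rng)
    alien_f1 = make_cross(founders2[:2], "one_way", gmap, other_rng)
    alien = self_to_generation(alien_f1, 1, 5, gmap, SelectionModel(), other_rng, "alien")
    dosage = panel.dosage.copy()
    dosage[:, 7] = alien.dosage[:, 0]
    panel2 = build_panel(
        [m.chromosome for m in panel.markers],
        dosage,
        positions=[m.position for m in panel.markers],
        marker_ids=panel.marker_ids,
    )
    kept2, removed2 = pca_outlier_filter(panel2, outlier_sd=3.0)
    assert removed2 == ["s7"]
    # an extreme threshold keeps everyone
    kept3, removed3 = pca_outlier_filter(panel2, outlier_sd=1e6)
    assert removed3 == []


def test_pca_outlier_filter_small_family_warns(rng):
    panel = build_panel(["1A", "2B"], rng.choice([0.0, 2.0], size=(2, 3)))
    with pytest.warns(UserWarning, match="too small"):
        kept, removed = pca_outlier_filter(panel)
    assert kept == panel.sample_ids and removed == []


def _mk(mid, chrom, pos):
    return MarkerRecord(mid, chrom, pos, "A", "C")


def _hit(markers, a, b, r2=1.0, fams=2):
    return PairHit(a, b, {f"F{i}": r2 for i in range(fams)}, fams, r2)


def test_group_regions_gap_rule():
    markers = {
        "a1": _mk("a1", "1A", 1_000_000),
        "a2": _mk("a2", "1A", 2_000_000),
        "a3": _mk("a3", "1A", 50_000_000),
        "b1": _mk("b1", "4A", 5_000_000),
    }
    hits = [_hit(markers, "a1", "b1"), _hit(markers, "a2", "b1"), _hit(markers, "a3", "b1")]
    regions, interactions = group_regions(hits, markers, region_gap_bp=10_000_000)
    by_chrom = {}
    for r in regions:
        by_chrom.setdefault(r.chromosome, []).append(r)
    assert sorted(len(r.member_markers) for r in by_chrom["1A"]) == [1, 2]
    assert len(by_chrom["4A"]) == 1
    assert len(interactions) == 2  # {a1,a2}x{b1} and {a3}x{b1}
    assert sum(len(ia.member_pairs) for ia in interactions) == len(hits)


def test_group_regions_full_cross_connection():
    markers = {f"a{i}": _mk(f"a{i}", "1A", 1_000_000 + i * 10_000) for i in range(4)}
    markers |= {f"b{i}": _mk(f"b{i}", "4A", 2_000_000 + i * 10_000) for i in range(3)}
    hits = [_hit(markers, a, b) for a in ("a0", "a1", "a2", "a3") for b in ("b0", "b1", "b2")]
    regions, interactions = group_regions(hits, markers, 10_000_000)
    assert len(regions) == 2
    assert len(interactions) == 1
    assert len(interactions[0].member_pairs) == 12


def test_group_regions_partition_property(rng):
    """Every hit marker lands in exactly one region; hits are conserved."""
    chrom_pool = ["1A", "2B", "3D", "5A"]
    markers = {}
    for i in range(30):
        markers[f"m{i}"] = _mk(f"m{i}", chrom_pool[i % 4], int(rng.integers(1, 2e8)))
    pairs = set()
    while len(pairs) < 25:
        a, b = rng.choice(30, size=2, replace=False)
        ma, mb = f"m{a}", f"m{b}"
        if markers[ma].chromosome != markers[mb].chromosome:
            pairs.add(tuple(sorted((ma, mb))))
    hits = [_hit(markers, a, b) for a, b in sorted(pairs)]
    regions, interactions = group_regions(hits, markers, region_gap_bp=20_000_000)
    member_all = [m for r in regions for m in r.member_markers]
    assert len(member_all) == len(set(member_all))
    assert set(member_all) == {m for h in hits for m in (h.marker_a, h.marker_b)}
    assert sum(len(ia.member_pairs) for ia in interactions) == len(hits)
    for r in regions:
        assert all(markers[m].chromosome == r.chromosome for m in r.member_markers)
        pos = [markers[m].position for m in r.member_markers]
        assert r.start == min(pos) and r.end == max(pos)


def _region(rid, chrom, start=1):
    return Region(rid, chrom, start, start + 1000, [f"{rid}_m"])


def _interaction(ra, rb):
    return Interaction(f"{ra.region_id}x{rb.region_id}", (ra, rb), [])


def test_detect_multiway_triangle_and_chain():
    r2d, r3b, r4a = _region("2D:1", "2D"), _region("3B:1", "3B"), _region("4A:1", "4A")
    triangle = [_interaction(r2d, r3b), _interaction(r3b, r4a), _interaction(r2d, r4a)]
    out = detect_multiway(triangle)
    three_way = [ia for ia in out if ia.k == 3]
    assert len(three_way) == 1
    assert {r.chromosome for r in three_way[0].regions} == {"2D", "3B", "4A"}
    assert len([ia for ia in out if ia.k == 2]) == 3  # pairwise components kept
    chain = [_interaction(r2d, r3b), _interaction(r3b, r4a)]
    assert all(ia.k == 2 for ia in detect_multiway(chain))


def test_detect_multiway_matches_bruteforce_cliques(rng):
    chrom_pool = ["1A", "2B", "3D", "4A", "5B", "6D"]
    for trial in range(10):
        n = int(rng.integers(4, 12))
        regions = [_region(f"{chrom_pool[i % 6]}:{i}", chrom_pool[i % 6]) for i in range(n)]
        edges = set()
        for a, b in itertools.combinations(range(n), 2):
            if regions[a].chromosome != regions[b].chromosome and rng.random() < 0.4:
                edges.add((a, b))
        interactions = [_interaction(regions[a], regions[b]) for a, b in sorted(edges)]
        got = {
            frozenset(r.region_id for r in ia.regions)
            for ia in detect_multiway(interactions)
            if ia.k == 3
        }
        want = set()
        for a, b, c in itertools.combinations(range(n), 3):
            if (
                {(a, b), (a, c), (b, c)} <= edges
                and len({regions[i].chromosome for i in (a, b, c)}) == 3
            ):
                want.add(frozenset(regions[i].region_id for i in (a, b, c)))
        assert got == want


def test_select_candidates_monotone_in_thresholds(rng):
    panel, _ = _random_family_fixture(rng, n_markers=10, n_families=3, fam_size=8)
    markers = {m.marker_id: m for m in panel.markers}
    fams = panel.split_families()
    prev = None
    for r2f, r2c, mf in [(0.5, 0.5, 2), (0.7, 0.6, 2), (0.9, 0.8, 2), (0.9, 0.8, 3)]:
        fam_result = per_family_screen(fams, r2f)
        combined = combined_screen(panel, r2c)
        got = {
            tuple(sorted((h.marker_a, h.marker_b)))
            for h in select_candidates(fam_result, combined, markers, mf)
        }
        if prev is not None:
            assert got <= prev
        prev = got
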