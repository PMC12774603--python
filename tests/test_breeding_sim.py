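"""Founders, meiosis, crossing, SSD selfing, viability selection, experiments."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from signepi.breeding_sim import (
    AttritionError,
    IndividualGenome,
    SelectionModel,
    SimConfig,
    apply_viability_selection,
    cohort_to_panel,
    default_wheat_map,
    drift_null_experiment,
    make_cross,
    meiosis_gamete,
    sample_crossover_positions,
    self_once,
    simulate_families,
    single_seed_descent,
    survival_probability,
    synth_founders,
)
from signepi.genotype_io import read_hapmap, write_hapmap


def _small_cfg(**kw):
    defaults = dict(n_founders=20, n_markers_per_chrom=20, n_chromosomes=4)
    defaults.update(kw)
    return SimConfig(**defaults)


def test_founders_are_inbred_and_reproducible():
    cfg = _small_cfg()
    gmap = cfg.build_map()
    a = synth_founders(cfg, gmap, np.random.default_rng(7))
    b = synth_founders(cfg, gmap, np.random.default_rng(7))
    for fa, fb in zip(a, b):
        assert fa.is_inbred()
        for ha, hb in zip(fa.haplotypes, fb.haplotypes):
            np.testing.assert_array_equal(ha, hb)


def test_founder_maf_spectrum():
    """Founder-pool MAF follows the configured uniform spectrum (KS check)."""
    cfg = SimConfig(
        n_founders=400, n_markers_per_chrom=5000, n_chromosomes=1, maf_spectrum=(0.1, 0.5)
    )
    gmap = cfg.build_map()
    founders = synth_founders(cfg, gmap, np.random.default_rng(3))
    freqs = np.mean([f.haplotypes[0][0] for f in founders], axis=0)
    maf = np.minimum(freqs, 1 - freqs)
    # sampling noise of 400 founders folds frequencies near 0.5; compare to the
    # folded distribution of Uniform(0.1, 0.5) with a loose KS tolerance
    ks = stats.kstest(maf, stats.uniform(loc=0.1, scale=0.4).cdf).statistic
    assert ks < 0.05


def test_mosaic_founders_are_inbred():
    cfg = _small_cfg(n_ancestral_haplotypes=4)
    gmap = cfg.build_map()
    founders = synth_founders(cfg, gmap, np.random.default_rng(1))
    assert all(f.is_inbred() for f in founders)


def test_crossover_count_is_poisson_mean():
    rng = np.random.default_rng(2)
    counts = [sample_crossover_positions(1.0, rng).size for _ in range(10_000)]
    se = np.sqrt(1.0 / 10_000)
    assert abs(np.mean(counts) - 1.0) < 3 * se


def test_zero_length_chromosome_gamete_is_parental():
    gmap = default_wheat_map(n_markers_per_chrom=10, chrom_length_morgans=0.0, n_chromosomes=1)
    hap0 = np.zeros(10, dtype=np.uint8)
    hap1 = np.ones(10, dtype=np.uint8)
    parent = IndividualGenome([np.vstack([hap0, hap1])])
    rng = np.random.default_rng(0)
    for _ in range(20):
        g = meiosis_gamete(parent, gmap, rng)[0]
        assert np.array_equal(g, hap0) or np.array_equal(g, hap1)


def test_recombination_fraction_matches_haldane():
    """Realized recombination between markers 0.5 Morgans apart matches the
    Haldane map function (1 - e^-1)/2 ~ 0.316."""
    gmap = default_wheat_map(n_markers_per_chrom=2, chrom_length_morgans=0.5, n_chromosomes=1)
    hap0 = np.zeros(2, dtype=np.uint8)
    hap1 = np.ones(2, dtype=np.uint8)
    parent = IndividualGenome([np.vstack([hap0, hap1])])
    rng = np.random.default_rng(4)
    n = 10_000
    rec = 0
    for _ in range(n):
        g = meiosis_gamete(parent, gmap, rng)[0]
        rec += g[0] != g[1]
    expected = (1 - np.exp(-2 * 0.5)) / 2
    se = np.sqrt(expected * (1 - expected) / n)
    assert abs(rec / n - expected) < 3 * se


def test_one_way_cross_is_mendelian():
    cfg = _small_cfg()
    gmap = cfg.build_map()
    p0 = IndividualGenome([np.zeros((2, 20), np.uint8) for _ in range(4)])
    p2 = IndividualGenome([np.ones((2, 20), np.uint8) for _ in range(4)])
    child = make_cross([p0, p2], "one_way", gmap, np.random.default_rng(0))
    np.testing.assert_array_equal(child.dosage(), np.ones(80))


def test_three_way_cross_carries_p3_gamete():
    cfg = _small_cfg()
    gmap = cfg.build_map()
    rng = np.random.default_rng(1)
    founders = synth_founders(cfg, gmap, rng)
    p3 = IndividualGenome([np.ones((2, 20), np.uint8) for _ in range(4)])
    child = make_cross([founders[0], founders[1], p3], "three_way", gmap, rng)
    assert np.all(child.dosage() >= 1)
    with pytest.raises(ValueError):
        make_cross([founders[0], founders[1]], "three_way", gmap, rng)


def test_cross_allele_frequency_conservation():
    """Without selection, mean offspring dosage over replicate crosses equals
    the parental mean at every marker."""
    cfg = _small_cfg(n_chromosomes=2)
    gmap = cfg.build_map()
    rng = np.random.default_rng(9)
    founders = synth_founders(cfg, gmap, rng)
    pa, pb = founders[0], founders[1]
    mid = (pa.dosage() + pb.dosage()) / 2.0
    mean = np.zeros_like(mid, dtype=float)
    n = 1000
    for _ in range(n):
        mean += make_cross([pa, pb], "one_way", gmap, rng).dosage()
    mean /= n
    # each offspring dosage is the midparent exactly for inbred parents
    np.testing.assert_allclose(mean, mid, atol=1e-12)


def test_f5_heterozygosity_is_one_sixteenth():
    """Loci segregating in the F1 retain (1/2)^4 heterozygosity at F5."""
    cfg = _small_cfg(n_chromosomes=8, n_markers_per_chrom=25)
    gmap = cfg.build_map()
    rng = np.random.default_rng(12)
    p0 = IndividualGenome([np.zeros((2, 25), np.uint8) for _ in range(8)])
    p2 = IndividualGenome([np.ones((2, 25), np.uint8) for _ in range(8)])
    f1 = make_cross([p0, p2], "one_way", gmap, rng)
    cohort, deaths = single_seed_descent(f1, 400, 5, gmap, SelectionModel(), rng)
    assert deaths == 0
    het = np.mean([np.mean(ind.dosage() == 1) for ind in cohort])
    assert het == pytest.approx(0.0625, abs=0.005)


def test_selection_s0_matches_none_seed_for_seed():
    base = _small_cfg(n_crosses=4, family_size=6, seed=42)
    null_model = SelectionModel(mode="none")
    s0 = SelectionModel(
        mode="epistatic", loci=("1A_0005", "2A_0005"),
        favored_combinations=((0, 0), (1, 1)), s=0.0,
    )
    pa, _ = simulate_families(SimConfig(**{**base.__dict__, "selection": null_model}))
    pb, _ = simulate_families(SimConfig(**{**base.__dict__, "selection": s0}))
    np.testing.assert_array_equal(pa.dosage, pb.dosage)
    assert pa.sample_ids == pb.sample_ids


def test_simulation_is_bit_reproducible():
    cfg = _small_cfg(n_crosses=3, family_size=5, seed=99)
    pa, ia = simulate_families(cfg)
    pb, ib = simulate_families(cfg)
    np.testing.assert_array_equal(pa.dosage, pb.dosage)
    assert ia == ib


def test_apply_viability_selection_rules():
    gmap = default_wheat_map(n_markers_per_chrom=3, n_chromosomes=2)
    model = SelectionModel(
        mode="epistatic", loci=("1A_0001", "1B_0001"),
        favored_combinations=((0, 0), (1, 1)), s=1.0, h=0.0,
    )

    def ind(da, db):
        haps = [np.zeros((2, 3), np.uint8), np.zeros((2, 3), np.uint8)]
        haps[0][:, 1] = (da >= 1, da == 2)
        haps[1][:, 1] = (db >= 1, db == 2)
        return IndividualGenome(haps)

    cohort = [ind(a, b) for a in (0, 1, 2) for b in (0, 1, 2)]
    rng = np.random.default_rng(0)
    survivors = apply_viability_selection(cohort, model, gmap, rng)
    combos = {(i.dosage_at(gmap.locus("1A_0001")), i.dosage_at(gmap.locus("1B_0001")))
              for i in survivors}
    assert (0, 2) not in combos and (2, 0) not in combos  # off homozygotes die
    assert {(0, 0), (2, 2)} <= combos
    assert len(survivors) == 7  # hets all survive at h=0
    # s=0 is the identity
    s0 = SelectionModel(mode="epistatic", loci=model.loci,
                        favored_combinations=model.favored_combinations, s=0.0)
    assert apply_viability_selection(cohort, s0, gmap, rng) == cohort


def test_additive_survival_probability():
    gmap = default_wheat_map(n_markers_per_chrom=3, n_chromosomes=1)
    model = SelectionModel(mode="additive", loci=("1A_0001",), favored_allele=1, s=0.5)

    def ind(d):
        h = np.zeros((2, 3), np.uint8)
        h[:, 1] = (d >= 1, d == 2)
        return IndividualGenome([h])

    assert survival_probability(ind(2), model, gmap) == 1.0
    assert survival_probability(ind(1), model, gmap) == 0.5
    assert survival_probability(ind(0), model, gmap) == 0.25


def test_f2_survival_seven_eighths():
    """F2 of complementary-fixed parents under s=1, h=0: the two off
    homozygote classes (1/16 each) die, so 7/8 survive."""
    gmap = default_wheat_map(n_markers_per_chrom=3, n_chromosomes=2)
    model = SelectionModel(
        mode="epistatic", loci=("1A_0001", "1B_0001"),
        favored_combinations=((0, 0), (1, 1)), s=1.0, h=0.0,
    )
    pa = IndividualGenome([np.zeros((2, 3), np.uint8), np.zeros((2, 3), np.uint8)])
    pb = IndividualGenome([np.ones((2, 3), np.uint8), np.ones((2, 3), np.uint8)])
    rng = np.random.default_rng(21)
    f1 = make_cross([pa, pb], "one_way", gmap, rng)
    n = 4000
    f2 = [self_once(f1, gmap, rng) for _ in range(n)]
    survivors = apply_viability_selection(f2, model, gmap, rng)
    rate = len(survivors) / n
    se = np.sqrt((7 / 8) * (1 / 8) / n)
    assert abs(rate - 7 / 8) < 3 * se


def test_ssd_with_lethal_selection_leaves_only_favored_combinations():
    gmap = default_wheat_map(n_markers_per_chrom=3, n_chromosomes=2)
    loci = ("1A_0001", "1B_0001")
    model = SelectionModel(
        mode="epistatic", loci=loci, favored_combinations=((0, 0), (1, 1)), s=1.0, h=0.0
    )
    pa = IndividualGenome([np.zeros((2, 3), np.uint8), np.zeros((2, 3), np.uint8)])
    pb = IndividualGenome([np.ones((2, 3), np.uint8), np.ones((2, 3), np.uint8)])
    rng = np.random.default_rng(8)
    f1 = make_cross([pa, pb], "one_way", gmap, rng)
    cohort, deaths = single_seed_descent(f1, 50, 5, gmap, model, rng, redraw_budget=5000)
    assert deaths > 0
    for ind in cohort:
        da = ind.dosage_at(gmap.locus(loci[0]))
        db = ind.dosage_at(gmap.locus(loci[1]))
        if 1 not in (da, db):
            assert (da // 2, db // 2) in ((0, 0), (1, 1))


def test_attrition_budget_exhaustion_raises():
    gmap = default_wheat_map(n_markers_per_chrom=3, n_chromosomes=2)
    model = SelectionModel(
        mode="epistatic", loci=("1A_0001", "1B_0001"),
        favored_combinations=((0, 0), (1, 1)), s=1.0, h=1.0,  # hets lethal too
    )
    pa = IndividualGenome([np.zeros((2, 3), np.uint8), np.zeros((2, 3), np.uint8)])
    pb = IndividualGenome([np.ones((2, 3), np.uint8), np.ones((2, 3), np.uint8)])
    rng = np.random.default_rng(0)
    f1 = make_cross([pa, pb], "one_way", gmap, rng)
    with pytest.raises(AttritionError):
        single_seed_descent(f1, 50, 5, gmap, model, rng, redraw_budget=3)


def test_exported_panel_roundtrips_through_hapmap(tmp_path):
    """Simulator panels survive a HapMap write/read: metadata exactly, dosages
    up to the minor-allele recoding a fresh read applies per marker."""
    cfg = _small_cfg(n_crosses=2, family_size=6, seed=5)
    panel, _ = simulate_families(cfg)
    path = tmp_path / "sim.hmp.txt"
    write_hapmap(panel, path, metadata_path=tmp_path / "sim.meta.tsv")
    back = read_hapmap(path, metadata=tmp_path / "sim.meta.tsv")
    assert back.marker_ids == panel.marker_ids
    assert back.sample_ids == panel.sample_ids
    assert [s.family_id for s in back.samples] == [s.family_id for s in panel.samples]
    for i in range(panel.n_markers):
        same = np.array_equal(back.dosage[i], panel.dosage[i], equal_nan=True)
        flipped = np.array_equal(back.dosage[i], 2.0 - panel.dosage[i], equal_nan=True)
        assert same or flipped


def test_drift_null_empty_design():
    cfg = _small_cfg(n_crosses=0)
    report = drift_null_experiment(cfg)
    assert report.n_families == 0 and report.n_candidates == 0


def test_cohort_to_panel_dosages_match_haplotypes():
    cfg = _small_cfg()
    gmap = cfg.build_map()
    rng = np.random.default_rng(2)
    founders = synth_founders(cfg, gmap, rng)
    panel = cohort_to_panel(founders[:3], gmap, "fam", stage="EYN")
    assert panel.n_samples == 3 and panel.n_markers == gmap.n_markers
    assert {s.stage for s in panel.samples} == {"EYN"}
    # founders are inbred: dosages are 0 or 2 only
    assert set(np.unique(panel.dosage)) <= {0.0, 2.0}
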