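"""Breeding-population and trait simulation: meiosis, DH/RIL, architectures."""

import numpy as np
import pytest

from gsel.io import GeneticMap
from gsel.simulate import (
    CrossPlan,
    TraitArchitecture,
    draw_architecture,
    mean_junction_count,
    meiotic_gamete,
    random_cross_plan,
    shared_subsets,
    shared_subsets_overlap,
    simulate_field_trial,
    simulate_founders,
    simulate_population,
    simulate_trait,
    study_populations,
    uniform_map,
)


class TestFounders:
    def test_deterministic_given_seed(self, small_map):
        a = simulate_founders(10, small_map, seed=5)
        b = simulate_founders(10, small_map, seed=5)
        np.testing.assert_array_equal(a.haplotypes, b.haplotypes)

    def test_fixed_frequency_one(self, small_map):
        f = simulate_founders(5, small_map, freq_spec=1.0, seed=1)
        assert (f.haplotypes == 1).all()

    def test_expected_hamming_distance_at_half_frequency(self):
        # two parents at freq 0.5 differ at each marker w.p. 0.5
        gmap = uniform_map(1, 100.0, 100)
        dists = [
            np.sum(
                np.ptp(simulate_founders(2, gmap, freq_spec=0.5, seed=s).haplotypes, axis=0)
            )
            for s in range(30)
        ]
        assert np.mean(dists) == pytest.approx(50, abs=5)

    def test_too_few_parents(self, small_map):
        with pytest.raises(ValueError):
            simulate_founders(1, small_map)


class TestMeiosis:
    def test_zero_distance_coinherited(self):
        gmap = GeneticMap({"a": ("1", 5.0), "b": ("1", 5.0)})
        hap_a, hap_b = np.array([0, 0]), np.array([1, 1])
        rng = np.random.default_rng(0)
        for _ in range(200):
            g = meiotic_gamete(hap_a, hap_b, gmap, rng)
            assert g[0] == g[1]

    def test_large_distance_approaches_half(self):
        gmap = GeneticMap({"a": ("1", 0.0), "b": ("1", 10000.0)})
        rng = np.random.default_rng(1)
        rec = sum(
            g[0] != g[1]
            for g in (
                meiotic_gamete(np.array([0, 0]), np.array([1, 1]), gmap, rng)
                for _ in range(4000)
            )
        )
        assert rec / 4000 == pytest.approx(0.5, abs=0.03)

    def test_haldane_ten_cM(self):
        # closed form: r = 0.5 * (1 - exp(-0.2)) = 0.090634...
        gmap = GeneticMap({"a": ("1", 0.0), "b": ("1", 10.0)})
        rng = np.random.default_rng(2)
        rec = sum(
            g[0] != g[1]
            for g in (
                meiotic_gamete(np.array([0, 0]), np.array([1, 1]), gmap, rng)
                for _ in range(10000)
            )
        )
        assert rec / 10000 == pytest.approx(0.5 * (1 - np.exp(-0.2)), abs=0.01)

    def test_marker_not_on_map_errors(self):
        gmap = GeneticMap({"a": ("1", 0.0)})
        with pytest.raises(ValueError, match="not on the genetic map"):
            meiotic_gamete(np.array([0, 0]), np.array([1, 1]), gmap, 0, marker_ids=["a", "zzz"])


class TestPopulations:
    def test_dh_from_identical_parents(self, small_map):
        f = simulate_founders(2, small_map, freq_spec=1.0, seed=1)
        plan = CrossPlan([("P000", "P001", 5)], line_type="DH")
        m = simulate_population(f, plan, seed=2)
        assert (m.genotypes == 1).all()

    def test_line_count_matches_plan(self, founders):
        plan = random_cross_plan(founders.parent_ids, 8, (8, 10), "DH", seed=9)
        m = simulate_population(founders, plan, seed=10)
        assert m.n_lines == plan.n_lines
        assert 64 <= m.n_lines <= 80

    def test_selfing_cross_rejected(self):
        with pytest.raises(ValueError, match="selfing cross"):
            CrossPlan([("P1", "P1", 4)])

    def test_determinism(self, founders):
        plan = random_cross_plan(founders.parent_ids, 4, 5, "RIL", seed=1)
        a = simulate_population(founders, plan, seed=2)
        b = simulate_population(founders, plan, seed=2)
        np.testing.assert_array_equal(a.genotypes, b.genotypes)

    def test_dh_segregation_half(self, small_map):
        # parents fixed for opposite alleles: DH allele frequency ~ 0.5
        f = simulate_founders(2, small_map, freq_spec=0.5, seed=3)
        seg = f.haplotypes[0] != f.haplotypes[1]
        plan = CrossPlan([("P000", "P001", 400)], line_type="DH")
        m = simulate_population(f, plan, seed=4)
        freqs = m.genotypes[:, seg].mean(axis=0)
        # pooled across segregating markers; binomial CI at n=400
        assert abs(freqs.mean() - 0.5) < 0.05

    def test_ril_doubles_recombination(self, founders, small_map):
        planD = random_cross_plan(founders.parent_ids, 20, 10, "DH", seed=5)
        planR = random_cross_plan(founders.parent_ids, 20, 10, "RIL", selfing_generations=8, seed=6)
        _, ancD = simulate_population(founders, planD, seed=7, return_ancestry=True)
        _, ancR = simulate_population(founders, planR, seed=8, return_ancestry=True)
        jD = mean_junction_count(ancD, small_map, founders.marker_ids)
        jR = mean_junction_count(ancR, small_map, founders.marker_ids)
        assert 1.6 < jR / jD < 2.2

    def test_marker_sharing_between_overlapping_populations(self):
        pa, pb, _ = study_populations(seed=11)
        both = (pa.polymorphic_mask() & pb.polymorphic_mask()).sum()
        assert 1000 <= both <= 1300
        assert pa.n_markers == 2520


class TestArchitecture:
    def test_exhaustive_draw(self):
        arch = draw_architecture(np.arange(10), 10, 1.0, seed=0)
        assert sorted(arch.qtl_marker_indices) == list(range(10))

    def test_too_many_qtl(self):
        with pytest.raises(ValueError, match="exceeds"):
            draw_architecture(np.arange(5), 10, 1.0, seed=0)

    def test_effect_moments(self):
        effects = np.concatenate(
            [draw_architecture(np.arange(500), 100, 1.5, seed=s).effects for s in range(100)]
        )
        assert effects.mean() == pytest.approx(0.0, abs=0.05)
        assert effects.var() == pytest.approx(1.5**2, rel=0.05)

    def test_duplicate_indices_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            TraitArchitecture([1, 1], [0.5, 0.5])


class TestSharedSubsets:
    def test_full_fraction_identical(self):
        arch = draw_architecture(np.arange(200), 100, 1.0, seed=1)
        a, b = shared_subsets(arch, 1.0, seed=2)
        assert sorted(a.qtl_marker_indices) == sorted(b.qtl_marker_indices) == sorted(
            arch.qtl_marker_indices
        )

    @pytest.mark.parametrize("fraction,expected_overlap,tol", [(0.5, 25, 3), (0.1, 1, 0.5)])
    def test_expected_overlap(self, fraction, expected_overlap, tol):
        # independent draws of size k overlap in k^2/n QTLs on average
        arch = draw_architecture(np.arange(300), 100, 1.0, seed=3)
        rng = np.random.default_rng(4)
        overlaps = []
        for _ in range(300):
            a, b = shared_subsets(arch, fraction, rng)
            overlaps.append(len(set(a.qtl_marker_indices) & set(b.qtl_marker_indices)))
        assert np.mean(overlaps) == pytest.approx(expected_overlap, abs=tol)

    def test_effects_preserved(self):
        arch = draw_architecture(np.arange(100), 50, 1.0, seed=5)
        table = dict(zip(arch.qtl_marker_indices.tolist(), arch.effects))
        a, _ = shared_subsets(arch, 0.4, seed=6)
        for idx, eff in zip(a.qtl_marker_indices, a.effects):
            assert table[int(idx)] == eff

    def test_explicit_overlap_scheme(self):
        arch = draw_architecture(np.arange(300), 100, 1.0, seed=7)
        a, b = shared_subsets_overlap(arch, 0.5, 0.4, seed=8)
        shared = set(a.qtl_marker_indices) & set(b.qtl_marker_indices)
        assert len(a.qtl_marker_indices) == len(b.qtl_marker_indices) == 50
        assert len(shared) == 20

    def test_overlap_infeasible(self):
        arch = draw_architecture(np.arange(100), 100, 1.0, seed=9)
        with pytest.raises(ValueError, match="cannot place"):
            shared_subsets_overlap(arch, 0.8, 0.0, seed=10)


class TestSimulateTrait:
    def test_h2_one_is_noiseless(self, dh_pop):
        poly = np.flatnonzero(dh_pop.polymorphic_mask())
        arch = draw_architecture(poly, 20, 1.0, seed=1, h2=1.0)
        y, g = simulate_trait(dh_pop, arch, seed=2)
        np.testing.assert_array_equal(y, g)

    def test_null_architecture_constant(self, dh_pop):
        arch = TraitArchitecture([0, 1], [0.0, 0.0], h2=1.0)
        y, g = simulate_trait(dh_pop, arch, seed=3)
        assert np.ptp(y) == 0

    def test_zero_variance_with_noise_errors(self, dh_pop):
        arch = TraitArchitecture([0, 1], [0.0, 0.0], h2=0.5)
        with pytest.raises(ValueError, match="zero"):
            simulate_trait(dh_pop, arch, seed=4)

    def test_realized_heritability(self, dh_pop):
        poly = np.flatnonzero(dh_pop.polymorphic_mask())
        rng = np.random.default_rng(5)
        ratios = []
        for _ in range(60):
            arch = draw_architecture(poly, 20, 1.0, rng, h2=0.6)
            y, g = simulate_trait(dh_pop, arch, rng)
            ratios.append(np.var(g, ddof=1) / np.var(y, ddof=1))
        assert np.mean(ratios) == pytest.approx(0.6, abs=0.05)


class TestFieldTrial:
    def test_controls_in_every_subblock(self):
        table = simulate_field_trial({f"L{i}": float(i) for i in range(40)}, seed=1)
        df = table.records
        for (loc, block), sub in df.groupby(["location", "sub_block"]):
            assert sub["is_control"].any()
        assert df["location"].nunique() == 3
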