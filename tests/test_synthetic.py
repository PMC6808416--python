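import numpy as np
import pytest

from splicehet import (
    GeneratorParams,
    MixtureSpec,
    generate_normal_profile,
    group_junctions,
    perturb_profile,
    run_entropy_experiment,
    run_mixture_experiment,
    sith_pair,
    spearman,
    synthesize_mixture,
)
from splicehet.divergence import usage_distribution, jsd
from splicehet.synthetic import (
    generate_gene_models,
    junction_profile_from_fractions,
    sample_isoform_fractions,
)

from conftest import make_profile


class TestGenerateNormalProfile:
    def test_deterministic_given_seed(self):
        params = GeneratorParams(n_units=50, seed=1)
        assert generate_normal_profile(params) == generate_normal_profile(params)

    def test_grouping_recovers_designed_units(self):
        params = GeneratorParams(n_units=100, members_range=(2, 4), seed=3)
        profile = generate_normal_profile(params)
        units = group_junctions(profile.junctions)
        assert len(units) == 100
        assert all(2 <= len(u) <= 4 for u in units)
        # every unit passes the default filters: >= 2 members, >= 1 read
        assert all(
            sum(profile.count(k) for k in u.members) >= 1 for u in units
        )

    def test_empirical_fractions_approach_dirichlet_draw_at_high_depth(self):
        params = GeneratorParams(n_units=20, depth=1e5, seed=11)
        profile, usages = generate_normal_profile(params, return_usage=True)
        units = group_junctions(profile.junctions)
        assert len(units) == len(usages)  # genomic order == construction order
        for unit, usage in zip(units, usages):
            counts = np.array([profile.count(k) for k in unit.members])
            np.testing.assert_allclose(counts / counts.sum(), usage, atol=0.01)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            GeneratorParams(n_units=0)
        with pytest.raises(ValueError):
            GeneratorParams(depth=0)
        with pytest.raises(ValueError):
            GeneratorParams(perturbation_strength=0.0)


@pytest.fixture(scope="module")
def normal():
    return generate_normal_profile(GeneratorParams(n_units=60, seed=7))


class TestPerturbProfile:
    def test_strength_zero_reproduces_normal_usage(self, normal):
        cell = perturb_profile(normal, 0.0, seed=5)
        assert sith_pair(cell, normal).sith == pytest.approx(0.0, abs=1e-12)

    def test_distinct_seeds_give_distinct_cells(self, normal):
        a = perturb_profile(normal, 0.8, seed=1)
        b = perturb_profile(normal, 0.8, seed=2)
        assert a.junctions != b.junctions

    def test_divergence_monotone_in_strength(self, normal):
        scores = [
            sith_pair(perturb_profile(normal, s, seed=123), normal).sith
            for s in np.arange(0.1, 1.0, 0.1)
        ]
        assert all(b > a for a, b in zip(scores, scores[1:]))


class TestSynthesizeMixture:
    def test_hand_computed_blend(self):
        normal = make_profile("n", {("chr1", 1, 100, "+"): 100})
        cells = (
            make_profile("c1", {("chr1", 1, 100, "+"): 50}),
            make_profile("c2", {("chr1", 1, 100, "+"): 30}),
        )
        mix = synthesize_mixture(MixtureSpec(normal, cells, level=2))
        assert mix.junctions[("chr1", 1, 100, "+")] == pytest.approx(98.8)

    def test_level_zero_is_identity(self):
        normal = make_profile("n", {("chr1", 1, 100, "+"): 42})
        mix = synthesize_mixture(MixtureSpec(normal, (), level=0))
        assert mix.junctions == normal.junctions

    def test_junction_absent_in_all_cells_scales_by_retained_fraction(self):
        normal = make_profile("n", {("chr1", 1, 100, "+"): 40})
        cells = tuple(make_profile(f"c{i}", {("chr2", 1, 100, "+"): 10}) for i in range(10))
        mix = synthesize_mixture(MixtureSpec(normal, cells, level=10))
        assert mix.junctions[("chr1", 1, 100, "+")] == pytest.approx(0.9 * 40)

    def test_level_exceeding_pool_rejected(self):
        normal = make_profile("n", {("chr1", 1, 100, "+"): 1})
        with pytest.raises(ValueError):
            MixtureSpec(normal, (), level=1)

    def test_affine_combination_conserved_per_junction(self):
        """Independent per-junction loop over the full universe."""
        params = GeneratorParams(n_units=30, seed=21)
        normal = generate_normal_profile(params)
        cells = tuple(
            perturb_profile(normal, 0.8, seed=100 + i, sample_id=f"c{i}")
            for i in range(5)
        )
        level = 4
        mix = synthesize_mixture(MixtureSpec(normal, cells, level=level))
        universe = set(normal.junctions)
        for cell in cells[:level]:
            universe |= set(cell.junctions)
        for key in universe:
            expected = normal.count(key) * (1 - level / 100) + sum(
                c.count(key) for c in cells[:level]
            ) / 100
            assert mix.count(key) == pytest.approx(expected, abs=1e-12)


class TestMixtureExperiment:
    def test_row_count_and_determinism(self):
        params = GeneratorParams(n_units=40, seed=9)
        t1 = run_mixture_experiment(params, n_cells=6, n_levels=4, replicates=2)
        t2 = run_mixture_experiment(params, n_cells=6, n_levels=4, replicates=2)
        assert len(t1) == 8
        assert t1.equals(t2)

    def test_single_mixture_has_positive_sith(self):
        params = GeneratorParams(n_units=40, seed=13)
        table = run_mixture_experiment(params, n_cells=2, n_levels=1, replicates=1)
        assert len(table) == 1
        assert table["sith"].iloc[0] > 0

    def test_mean_sith_nondecreasing_in_level(self):
        params = GeneratorParams(n_units=100, seed=17)
        table = run_mixture_experiment(params, n_cells=12, n_levels=12, replicates=3)
        means = table.groupby("level")["sith"].mean().to_numpy()
        assert np.all(np.diff(means) > 0)

    def test_levels_cannot_exceed_cells(self):
        with pytest.raises(ValueError):
            run_mixture_experiment(GeneratorParams(seed=1), n_cells=3, n_levels=4)


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman([1, 2, 3], [10, 20, 30]) == 1.0
        assert spearman([1, 2, 3], [3, 2, 1]) == -1.0

    def test_hand_computed_rank_correlation(self):
        assert spearman([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 2], [1, 2])
        with pytest.raises(ValueError):
            spearman([1, 2, 3], [1, 2])
        with pytest.raises(ValueError):
            spearman([1, 1, 1], [1, 2, 3])


class TestEntropyExperiment:
    def test_fractions_follow_heterogeneity_level(self):
        genes = generate_gene_models(n_genes=3, seed=1)
        rng = np.random.default_rng(0)
        fr = sample_isoform_fractions(genes, 0.25, rng)
        for gene, f in zip(genes, fr):
            assert f.fractions[0] == pytest.approx(0.75)
            assert sum(f.fractions) == pytest.approx(1.0)

    def test_junction_counts_reflect_group_fractions(self):
        # one gene, two isoforms always split at every region; at high depth
        # the per-unit usage approaches the isoform fractions
        genes = generate_gene_models(n_genes=1, isoform_range=(2, 2), seed=2)
        rng = np.random.default_rng(3)
        fr = sample_isoform_fractions(genes, 0.3, rng)
        profile = junction_profile_from_fractions(genes, fr, depth=2e5, rng=rng)
        for unit in group_junctions(profile.junctions):
            if len(unit) < 2:
                continue
            counts = np.array([profile.count(k) for k in unit.members])
            assert sorted(usage_distribution(counts).tolist()) == pytest.approx(
                [0.3, 0.7], abs=0.01
            )

    def test_experiment_shape_and_determinism(self):
        a = run_entropy_experiment(n_samples=20, n_pools=2, seed=5)
        b = run_entropy_experiment(n_samples=20, n_pools=2, seed=5)
        assert len(a) == 20
        assert a.equals(b)
        assert (a["ith_transcript"] >= 0).all()
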