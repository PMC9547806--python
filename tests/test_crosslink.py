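"""Crosslinking-simulator laws, invariants and exact small-system behaviour."""

import dataclasses

import numpy as np
import pytest
from scipy import stats as sps

from clusterlab.crosslink import (
    AntibodySpecies,
    BindingParams,
    Stoichiometry,
    complement_proxy,
    component_stats,
    make_receptor_pool,
    place_receptors,
    saturating_antibody_count,
    simulate_binding,
    sweep_combinations,
    synergy_matrix,
)
from clusterlab.errors import InvalidArgumentError

from _oracles import enumerate_attachment_outcomes, union_find_component_sizes


def species(target, count, label=None):
    return AntibodySpecies(id=label or f"anti-{target}", target_subunit=target,
                           molecule_count=count)


class TestReceptorPool:
    def test_default_stoichiometry_has_two_alpha_epitopes(self):
        pool = make_receptor_pool(3)
        assert pool.n == 3
        assert pool.stoichiometry.counts["alpha"] == 2
        assert pool.stoichiometry.total_epitopes == 5

    def test_custom_stoichiometry(self):
        pool = make_receptor_pool(1, Stoichiometry({"alpha": 2}))
        assert pool.stoichiometry.total_epitopes == 2

    def test_zero_receptors_rejected(self):
        with pytest.raises(InvalidArgumentError):
            make_receptor_pool(0)

    def test_invalid_stoichiometry_rejected(self):
        with pytest.raises(InvalidArgumentError):
            Stoichiometry({"alpha": 0})
        with pytest.raises(InvalidArgumentError):
            Stoichiometry({"alpha": -1, "beta": 2})


class TestSimulateBinding:
    def test_no_species_leaves_all_singletons(self):
        graph = simulate_binding(make_receptor_pool(5), [], seed=0)
        stats = component_stats(graph)
        assert stats.component_sizes == (1, 1, 1, 1, 1)
        assert not graph.antibodies

    def test_unknown_target_subunit_rejected(self):
        with pytest.raises(InvalidArgumentError):
            simulate_binding(make_receptor_pool(2), [species("gamma", 5)], seed=0)

    @pytest.mark.parametrize("seed", range(20))
    def test_dimer_law_single_non_alpha_species(self, seed):
        """One non-alpha specificity: every receptor has one epitope, so
        components never exceed two receptors."""
        graph = simulate_binding(
            make_receptor_pool(40), [species("beta", 200)], seed=seed
        )
        assert component_stats(graph).max_size <= 2

    @pytest.mark.parametrize("seed", range(20))
    def test_chain_law_single_alpha_species(self, seed):
        """One anti-alpha specificity without intra-receptor binding: receptor
        degree <= 2, i.e. components are paths or cycles."""
        graph = simulate_binding(
            make_receptor_pool(40), [species("alpha", 200)], seed=seed
        )
        assert graph.receptor_degree().max() <= 2

    def test_occupancy_invariants_across_conditions(self):
        """No epitope bound twice, no antibody with more than two arms."""
        conditions = [
            [species("alpha", 30)],
            [species("beta", 80)],
            [species("alpha", 20), species("delta", 20)],
            [species("beta", 10), species("beta", 10, "anti-beta-2")],
        ]
        for seed, specs in enumerate(conditions):
            graph = simulate_binding(make_receptor_pool(25), specs, seed=seed)
            graph.validate()  # raises AssertionError on any breach

    def test_determinism_same_seed_identical_graph(self):
        pool = make_receptor_pool(30)
        specs = [species("alpha", 40), species("epsilon", 40)]
        g1 = simulate_binding(pool, specs, seed=99)
        g2 = simulate_binding(pool, specs, seed=99)
        assert [(a.species_id, a.attachments) for a in g1.antibodies] == \
            [(a.species_id, a.attachments) for a in g2.antibodies]
        g3 = simulate_binding(pool, specs, seed=100)
        assert [(a.species_id, a.attachments) for a in g3.antibodies] != \
            [(a.species_id, a.attachments) for a in g1.antibodies]

    def test_max_events_truncates_trajectory_prefix(self):
        pool = make_receptor_pool(20)
        specs = [species("alpha", 30)]
        full = simulate_binding(pool, specs, seed=5)
        part = simulate_binding(pool, specs,
                                BindingParams(max_events=3), seed=5)
        n_att = sum(len(a.attachments) for a in part.antibodies)
        assert n_att == 3
        full_events = [(a.species_id, tuple(a.attachments[:1])) for a in full.antibodies]
        part_events = [(a.species_id, tuple(a.attachments[:1])) for a in part.antibodies]
        assert part_events == full_events[: len(part_events)]

    def test_intra_receptor_binding_flag(self):
        """With the flag on, a single receptor's two alpha epitopes can be
        bridged by one antibody; off, the second arm stays free."""
        pool = make_receptor_pool(1)
        sp = [species("alpha", 1)]
        g_off = simulate_binding(pool, sp, BindingParams(allow_intra_receptor=False), seed=0)
        assert max(len(a.attachments) for a in g_off.antibodies) == 1
        g_on = simulate_binding(pool, sp, BindingParams(allow_intra_receptor=True,
                                                        k_cross=1e6), seed=0)
        assert max(len(a.attachments) for a in g_on.antibodies) == 2

    def test_acyclic_mode_yields_forest(self):
        params = BindingParams(allow_cycles=False, k_cross=50.0)
        for seed in range(5):
            graph = simulate_binding(make_receptor_pool(20),
                                     [species("alpha", 30), species("beta", 30)],
                                     params, seed=seed)
            g = graph.to_networkx()
            assert g.number_of_edges() == g.number_of_nodes() - \
                len(list(__import__("networkx").connected_components(g)))

    def test_geometric_mode_respects_capture_radius(self):
        pool = place_receptors(make_receptor_pool(60), density_per_um2=500.0, seed=1)
        params = BindingParams(mode="geometric", capture_radius=20.0, k_cross=100.0)
        graph = simulate_binding(pool, [species("alpha", 100)], params, seed=2)
        for r1, r2 in graph.receptor_edges():
            d = np.linalg.norm(pool.positions[r1] - pool.positions[r2])
            assert d <= 20.0 / 1000.0 + 1e-12

    def test_geometric_mode_requires_positions(self):
        with pytest.raises(InvalidArgumentError):
            simulate_binding(make_receptor_pool(5), [species("beta", 5)],
                             BindingParams(mode="geometric"), seed=0)


class TestComponentStats:
    def test_no_antibodies_all_singletons(self):
        stats = component_stats(simulate_binding(make_receptor_pool(5), [], seed=0))
        assert stats.max_size == 1 and stats.mean_size == 1.0

    def test_matches_union_find_oracle_on_random_graphs(self):
        for seed in range(10):
            graph = simulate_binding(
                make_receptor_pool(50),
                [species("alpha", 40), species("delta", 40)],
                seed=seed,
            )
            expected = tuple(union_find_component_sizes(50, graph.receptor_edges()))
            assert component_stats(graph).component_sizes == expected

    def test_fraction_ge_is_non_increasing_and_bounded(self):
        graph = simulate_binding(make_receptor_pool(60),
                                 [species("alpha", 60), species("beta", 60)], seed=3)
        stats = component_stats(graph)
        fracs = [stats.fraction_in_components_ge(k) for k in range(1, stats.max_size + 2)]
        assert fracs[0] == 1.0
        assert all(0.0 <= f <= 1.0 for f in fracs)
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))
        assert sum(stats.component_sizes) == 60


class TestComplementProxy:
    def test_all_singletons_zero(self):
        stats = component_stats(simulate_binding(make_receptor_pool(4), [], seed=0))
        assert complement_proxy(stats, 2) == 0.0

    def test_one_dimer_among_four(self):
        from clusterlab.crosslink import AggregateStats

        stats = AggregateStats(component_sizes=(2, 1, 1))
        assert complement_proxy(stats, 2) == 0.5

    def test_invalid_smin(self):
        from clusterlab.crosslink import AggregateStats

        with pytest.raises(InvalidArgumentError):
            complement_proxy(AggregateStats(component_sizes=(1,)), 0)

    def test_matches_direct_recount(self):
        for seed in range(5):
            graph = simulate_binding(make_receptor_pool(40),
                                     [species("alpha", 40), species("epsilon", 40)],
                                     seed=seed)
            stats = component_stats(graph)
            for s_min in (2, 4, 8):
                sizes = np.asarray(stats.component_sizes)
                expected = sizes[sizes >= s_min].sum() / sizes.sum()
                assert complement_proxy(stats, s_min) == pytest.approx(expected)


class TestSmallSystemOracle:
    def test_outcome_distribution_matches_enumeration(self):
        """4 receptors, 2 anti-alpha antibodies, k_on = k_cross: simulated
        outcome frequencies agree with exhaustive event-sequence enumeration
        (chi-square, alpha = 0.01)."""
        stoich = dict(DEFAULT := {"alpha": 2, "beta": 1, "delta": 1, "epsilon": 1})
        exact = enumerate_attachment_outcomes(
            4, stoich, [("alpha", 2)], k_on=1.0, k_cross=1.0
        )
        assert sum(exact.values()) == pytest.approx(1.0)
        params = BindingParams(k_on=1.0, k_cross=1.0)
        n_runs = 2500
        counts = {}
        pool = make_receptor_pool(4)
        specs = [species("alpha", 2)]
        for seed in range(n_runs):
            sig = component_stats(simulate_binding(pool, specs, params, seed=seed)) \
                .component_sizes
            key = tuple(sorted(sig))
            counts[key] = counts.get(key, 0) + 1
        exact_keyed = {tuple(sorted(k)): v for k, v in exact.items()}
        observed = np.array([counts.get(k, 0) for k in exact_keyed])
        expected = np.array([v * n_runs for v in exact_keyed.values()])
        # merge rare outcomes so every expected bin has >= 5 counts
        order = np.argsort(expected)
        obs_m, exp_m, o_acc, e_acc = [], [], 0.0, 0.0
        for i in order:
            o_acc += observed[i]
            e_acc += expected[i]
            if e_acc >= 5:
                obs_m.append(o_acc)
                exp_m.append(e_acc)
                o_acc = e_acc = 0.0
        obs_m[-1] += o_acc
        exp_m[-1] += e_acc
        res = sps.chisquare(obs_m, exp_m)
        assert res.pvalue > 0.01


class TestSweep:
    params = BindingParams()

    def test_single_species_panel(self):
        panel = [species("beta", 0)]
        df = sweep_combinations(50, panel, seeds=[0, 1], total_count=100)
        assert len(df) == 1
        assert df.iloc[0]["species_a"] == df.iloc[0]["species_b"] == "anti-beta"

    def test_empty_panel_rejected(self):
        with pytest.raises(InvalidArgumentError):
            sweep_combinations(50, [], seeds=[0])

    def test_same_subunit_pair_shows_no_enhancement(self):
        panel = [species("beta", 0, "b1"), species("beta", 0, "b2")]
        df = sweep_combinations(100, panel, seeds=range(10), total_count=200)
        singles = df[df.species_a == df.species_b]
        pair = df[df.species_a != df.species_b].iloc[0]
        best_single = singles["proxy_mean"].max()
        assert pair["proxy_mean"] <= best_single + 3 * (pair["proxy_sd"] + 1e-12)
        assert pair["mean_size_mean"] <= singles["mean_size_mean"].max() * 1.1 + 0.1

    def test_delta_epsilon_pair_exceeds_both_singles(self):
        panel = [species("delta", 0), species("epsilon", 0)]
        df = sweep_combinations(100, panel, seeds=range(10), total_count=200)
        singles = df[df.species_a == df.species_b]
        pair = df[df.species_a != df.species_b].iloc[0]
        assert pair["proxy_mean"] > singles["proxy_mean"].max()
        assert pair["mean_size_mean"] > singles["mean_size_mean"].max()

    def test_matrix_is_symmetric_with_singles_on_diagonal(self):
        panel = [species("alpha", 0), species("beta", 0)]
        df = sweep_combinations(60, panel, seeds=[0, 1], total_count=120)
        mat = synergy_matrix(df)
        assert np.allclose(mat.values, mat.values.T, equal_nan=True)
        assert not np.isnan(np.diag(mat.values)).any()

    def test_saturating_count_default(self):
        assert saturating_antibody_count(200) == 400
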