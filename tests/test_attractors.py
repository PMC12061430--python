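import numpy as np
import pytest

from hypoxemt import (
    SamplingConfig,
    descend_to_attractor,
    enumerate_attractors,
    export_attractor_table,
    random_boolean_network,
    read_attractor_table,
    sample_attractors,
)
from hypoxemt.attractors import canonical_cycle, expected_visited_distribution

EPITHELIAL = (0, 0, 1, 0, 1, 1)     # (EMT_signal, SNAI1, miR34, ZEB1, miR200, Ecadherin)
MESENCHYMAL_0 = (0, 1, 0, 1, 0, 0)
HYBRID = (1, 1, 0, 0, 1, 1)
MESENCHYMAL_1 = (1, 1, 0, 1, 0, 0)


class TestDescend:
    def test_toggle_two_cycle(self, toggle):
        attr, transient = descend_to_attractor(toggle, (0, 0))
        assert attr.states == ((0, 0), (1, 1))
        assert transient == 0

    def test_emt_all_off_reaches_epithelial_in_two(self, emt):
        attr, transient = descend_to_attractor(emt, (0,) * 6, {"EMT_signal": 0})
        assert attr.states == (EPITHELIAL,)
        assert transient == 2

    @pytest.mark.parametrize("signal", [0, 1])
    def test_mesenchymal_is_fixed_under_both_signals(self, emt, signal):
        state = emt.state_from({"EMT_signal": signal, "SNAI1": 1, "ZEB1": 1})
        attr, transient = descend_to_attractor(emt, state, {"EMT_signal": signal})
        assert attr.is_fixed_point and transient == 0
        assert attr.states[0][emt.index["ZEB1"]] == 1

    def test_canonicalization_merges_cycle_phases(self, toggle):
        a1, _ = descend_to_attractor(toggle, (0, 0))
        a2, _ = descend_to_attractor(toggle, (1, 1))
        assert a1.states == a2.states

    def test_canonical_cycle_starts_at_smallest(self):
        assert canonical_cycle([(1, 0), (0, 1)]) == ((0, 1), (1, 0))


class TestEnumerate:
    def test_toggle_three_attractors_with_exact_basins(self, toggle):
        attrs = enumerate_attractors(toggle)
        by_states = {a.states: a.basin_weight for a in attrs}
        assert by_states == {
            ((0, 1),): 0.25,
            ((1, 0),): 0.25,
            ((0, 0), (1, 1)): 0.5,
        }

    def test_emt_fixed_points_without_signal(self, emt):
        attrs = enumerate_attractors(emt, {"EMT_signal": 0})
        assert {a.states for a in attrs} == {(EPITHELIAL,), (MESENCHYMAL_0,)}

    def test_emt_fixed_points_with_signal(self, emt):
        attrs = enumerate_attractors(emt, {"EMT_signal": 1})
        assert {a.states for a in attrs} == {(HYBRID,), (MESENCHYMAL_1,)}

    def test_basins_sum_to_one(self, demo):
        attrs = enumerate_attractors(
            demo,
            {"Hypoxia": 0, "GF": 1, "TGFb_ext": 0, "Stiff_ECM": 1,
             "ECM_attached": 1, "Density_High": 0},
        )
        assert abs(sum(a.basin_weight for a in attrs) - 1.0) < 1e-9

    def test_cap_exceeded_directs_to_sampling(self):
        net = random_boolean_network(10, 2, n_inputs=0, seed=0)
        with pytest.raises(ValueError, match="sample_attractors"):
            enumerate_attractors(net, cap=5)


class TestSample:
    def test_toggle_sampling_finds_all_three(self, toggle):
        table = sample_attractors(toggle, SamplingConfig(T=25, p=0.02, N=200), seed=4)
        attrs = table.entries[0][1]
        assert {a.states for a in attrs} == {
            ((0, 1),), ((1, 0),), ((0, 0), (1, 1)),
        }
        # visited-state weights vs the symmetric stationary values
        n_visited = 200 * 26
        for a in attrs:
            expected = 0.5 if a.length == 2 else 0.25
            se = (expected * (1 - expected) / 200) ** 0.5  # trajectory-level SE
            assert abs(a.basin_weight - expected) <= 3 * se
        assert abs(sum(a.basin_weight for a in attrs) - 1.0) < 1e-9

    def test_environment_grid_size(self):
        net = random_boolean_network(10, 2, n_inputs=3, seed=1)
        envs = SamplingConfig(N=100).resolve_environments(net)
        assert len(envs) == 2**3
        # total initial conditions across environments: N * 2^inputs
        assert SamplingConfig(N=100).N * len(envs) == 800

    @pytest.mark.parametrize("seed", range(8))
    def test_sampled_subset_of_enumerated_with_recovery(self, seed):
        net = random_boolean_network(9, 2, n_inputs=1, seed=seed)
        for env in ({"I0": 0}, {"I0": 1}):
            enumerated = enumerate_attractors(net, env)
            sampled = sample_attractors(
                net, SamplingConfig(T=25, p=0.02, N=500, environments=(env,)), seed=seed
            ).entries[0][1]
            enum_states = {a.states for a in enumerated}
            samp_states = {a.states for a in sampled}
            assert samp_states <= enum_states
            big = {a.states for a in enumerated if a.basin_weight >= 0.05}
            assert big <= samp_states

    def test_sampling_deterministic_for_seed(self, toggle):
        cfg = SamplingConfig(T=10, p=0.05, N=50)
        t1 = sample_attractors(toggle, cfg, seed=9)
        t2 = sample_attractors(toggle, cfg, seed=9)
        assert export_attractor_table(t1) == export_attractor_table(t2)

    def test_weights_match_exact_visited_expectation(self):
        net = random_boolean_network(9, 2, n_inputs=1, seed=3)
        env = {"I0": 1}
        N = 500
        exact = expected_visited_distribution(net, env, T=25, p=0.02)
        sampled = sample_attractors(
            net, SamplingConfig(T=25, p=0.02, N=N, environments=(env,)), seed=42
        ).entries[0][1]
        for a in sampled:
            e = exact.get(a.states, 0.0)
            se = max((e * (1 - e) / N) ** 0.5, 1e-3)
            assert abs(a.basin_weight - e) <= 3 * se


class TestExport:
    def test_toggle_export_has_four_data_rows(self, toggle):
        from hypoxemt.attractors import AttractorTable

        table = AttractorTable(toggle, [({}, enumerate_attractors(toggle))])
        text = export_attractor_table(table)
        assert len(text.strip().splitlines()) == 1 + 4  # header + 2 FPs + 2-cycle x2

    def test_emt_export_covers_three_phenotype_states(self, emt, emt_sigs):
        from hypoxemt.attractors import AttractorTable
        from hypoxemt import classify_state

        table = AttractorTable(emt)
        for sig in (0, 1):
            env = {"EMT_signal": sig}
            table.entries.append((env, enumerate_attractors(emt, env)))
        phenos = {
            classify_state(a.states[0], emt_sigs, emt)["EMT"]
            for a in table.all_attractors()
        }
        assert phenos == {"Epithelial", "Hybrid", "Mesenchymal"}
        assert export_attractor_table(table)

    def test_round_trip_through_csv(self, emt):
        from hypoxemt.attractors import AttractorTable

        table = AttractorTable(emt)
        for sig in (0, 1):
            env = {"EMT_signal": sig}
            table.entries.append((env, enumerate_attractors(emt, env)))
        back = read_attractor_table(export_attractor_table(table), emt)
        for (e1, a1), (e2, a2) in zip(table.entries, back.entries):
            assert e1 == e2
            assert [a.states for a in a1] == [a.states for a in a2]
            assert np.allclose([a.basin_weight for a in a1],
                               [a.basin_weight for a in a2])

    def test_every_environment_has_an_attractor(self, emt):
        # a deterministic finite system always has at least one attractor
        for sig in (0, 1):
            assert enumerate_attractors(emt, {"EMT_signal": sig})
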