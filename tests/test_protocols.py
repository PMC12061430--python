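import dataclasses

import pandas as pd
import pytest

from hypoxemt import (
    Clamp,
    ExperimentSpec,
    GridAxis,
    Window,
    count_divisions,
    load_protocol,
    parse_model,
    resolve_initial_state,
    run_cascade_preset,
    run_experiment,
    run_grid,
    simulate_trajectory,
)
from hypoxemt.phenotypes import PhenotypeSignature, SignatureSet
from hypoxemt.protocols import cascade_windows

from conftest import BASE_ENV, EPI_ENV, SOFT_ENV


class TestResolveInitialState:
    def test_epithelial_without_signal(self, emt, emt_sigs):
        state = resolve_initial_state(emt, "Epithelial", {"EMT_signal": 0}, emt_sigs)
        assert emt.state_dict(state) == {
            "EMT_signal": 0, "SNAI1": 0, "miR34": 1, "ZEB1": 0, "miR200": 1, "Ecadherin": 1,
        }

    def test_hybrid_not_stable_without_signal(self, emt, emt_sigs):
        with pytest.raises(ValueError, match="no attractor"):
            resolve_initial_state(emt, "Hybrid", {"EMT_signal": 0}, emt_sigs)

    def test_mesenchymal_with_signal(self, emt, emt_sigs):
        state = resolve_initial_state(emt, "Mesenchymal", {"EMT_signal": 1}, emt_sigs)
        assert state[emt.index["ZEB1"]] == 1


class TestRunExperiment:
    def _detach_spec(self, demo, demo_sigs, hypoxia):
        # cells equilibrate on a soft ECM (normoxic or hypoxic), then detach
        plated = {**SOFT_ENV, "Hypoxia": hypoxia}
        windows = (
            Window(10, plated),
            Window(10, {**plated, "ECM_attached": 0}),
        )
        return ExperimentSpec(
            model=demo, windows=windows, signatures=demo_sigs,
            initial_phenotype="Epithelial", initial_env=plated,
            ensemble=20, death_signature="Apoptotic", seed=1,
        )

    def test_anoikis_on_detachment_under_normoxia(self, demo, demo_sigs):
        result = run_experiment(self._detach_spec(demo, demo_sigs, hypoxia=0))
        assert result.deaths == 20
        # death occurs within 3 steps of detachment
        for traj in result.trajectories:
            assert len(traj.states) <= 1 + 10 + 3

    def test_hypoxia_blocks_anoikis(self, demo, demo_sigs):
        result = run_experiment(self._detach_spec(demo, demo_sigs, hypoxia=1))
        assert result.deaths == 0

    def test_deterministic_rerun_identical(self, demo, demo_sigs, epithelial_start):
        spec = ExperimentSpec(
            model=demo, windows=(Window(20, BASE_ENV, noise=0.02),),
            signatures=demo_sigs, initial_state=epithelial_start,
            ensemble=10, seed=13,
        )
        r1, r2 = run_experiment(spec), run_experiment(spec)
        pd.testing.assert_frame_equal(r1.fractions, r2.fractions)
        pd.testing.assert_frame_equal(r1.node_means, r2.node_means)

    def test_continuous_mode_live_step_conservation(self, demo, demo_sigs, epithelial_start):
        spec = ExperimentSpec(
            model=demo, windows=(Window(25, BASE_ENV, noise=0.02),),
            signatures=demo_sigs, initial_state=epithelial_start,
            budget=500, death_signature="Apoptotic", seed=2,
        )
        result = run_experiment(spec)
        assert result.live_steps == 500

    def test_budget_smaller_than_first_window_errors(self, demo, demo_sigs, epithelial_start):
        spec = ExperimentSpec(
            model=demo, windows=(Window(100, BASE_ENV),),
            signatures=demo_sigs, initial_state=epithelial_start, budget=10,
        )
        with pytest.raises(ValueError, match="budget"):
            run_experiment(spec)

    def test_no_post_death_states(self, demo, demo_sigs):
        result = run_experiment(self._detach_spec(demo, demo_sigs, hypoxia=0))
        apo = demo.index["Apoptosis"]
        for traj in result.trajectories:
            # apoptosis appears at most once, and only as the final state
            assert all(s[apo] == 0 for s in traj.states[:-1])


class TestCascadePreset:
    EXPECTED = ["Epithelial", "Epithelial", "Mesenchymal", "Mesenchymal",
                "Mesenchymal", "Mesenchymal", "Epithelial"]

    def _dominant(self, result, window):
        f = result.fractions
        sub = f[(f.window == window) & (f.module == "EMT")]
        return sub.loc[sub.fraction.idxmax(), "phenotype"]

    def test_pulse_sequence(self, demo, demo_sigs):
        result = run_cascade_preset(demo, demo_sigs, ensemble=10)
        assert [self._dominant(result, w) for w in range(7)] == self.EXPECTED

    def test_circulating_mesenchymal_cells_survive(self, demo, demo_sigs):
        result = run_cascade_preset(demo, demo_sigs, ensemble=10)
        assert result.deaths == 0

    def test_high_density_blocks_hypoxic_emt_in_pulse_two(self, demo, demo_sigs):
        result = run_cascade_preset(demo, demo_sigs, ensemble=10)
        f = result.fractions
        mes = f[(f.window == 1) & (f.phenotype == "Mesenchymal")]
        assert float(mes.fraction.iloc[0]) == 0.0

    def test_breaking_autocrine_loop_in_circulation_kills(self, demo, demo_sigs):
        windows = list(cascade_windows(20))
        windows[4] = dataclasses.replace(
            windows[4], clamps={"TGFb_secr": Clamp("off", 1.0)}
        )
        spec = ExperimentSpec(
            model=demo, windows=tuple(windows), signatures=demo_sigs,
            initial_phenotype="Epithelial", initial_env=dict(windows[0].env),
            ensemble=10, death_signature="Apoptotic", seed=0,
        )
        result = run_experiment(spec)
        assert result.deaths == 10  # reverting cells undergo anoikis

    def test_missing_inputs_rejected(self, emt, emt_sigs):
        with pytest.raises(ValueError, match="inputs"):
            run_cascade_preset(emt, emt_sigs)


class TestGrids:
    def _base_spec(self, demo, demo_sigs, epithelial_start):
        # 10-step burn-in lets the transient settle; window 1 is measured
        return ExperimentSpec(
            model=demo, windows=(Window(10, BASE_ENV), Window(30, BASE_ENV)),
            signatures=demo_sigs, initial_state=epithelial_start,
            ensemble=5, seed=0,
        )

    @staticmethod
    def _settled(grid, phenotype, **levels):
        sub = grid[(grid.window == 1) & (grid.phenotype == phenotype)]
        for col, val in levels.items():
            sub = sub[sub[col] == val]
        return sub.fraction

    def test_vhl_loss_drives_emt_with_arrest(self, demo, demo_sigs, epithelial_start):
        spec = self._base_spec(demo, demo_sigs, epithelial_start)
        grid = run_grid(
            spec, [GridAxis("clamp", "VHL", (1.0,), mode="off")],
        )
        assert self._settled(grid, "Mesenchymal").iloc[0] > 0.95
        assert self._settled(grid, "Cycling").iloc[0] < 0.05

    def test_only_joint_myc_cyclin_d_rescues_cycling(self, demo, demo_sigs, epithelial_start):
        spec = self._base_spec(demo, demo_sigs, epithelial_start)
        backgrounds = {
            "VHL-": {"VHL": Clamp("off", 1.0)},
            "VHL-;Myc+": {"VHL": Clamp("off", 1.0), "Myc": Clamp("on", 1.0)},
            "VHL-;CycD+": {"VHL": Clamp("off", 1.0), "CyclinD": Clamp("on", 1.0)},
            "VHL-;Myc+;CycD+": {"VHL": Clamp("off", 1.0), "Myc": Clamp("on", 1.0),
                                 "CyclinD": Clamp("on", 1.0)},
        }
        grid = run_grid(spec, [GridAxis("env", "Hypoxia", (0,))], backgrounds)
        cycling = (
            grid[(grid.phenotype == "Cycling") & (grid.window == 1)]
            .set_index("background").fraction
        )
        assert cycling["VHL-"] < 0.05
        assert cycling["VHL-;Myc+"] < 0.05
        assert cycling["VHL-;CycD+"] < 0.05
        assert cycling["VHL-;Myc+;CycD+"] > 0.95

    def test_single_point_grid_equals_run_experiment(self, demo, demo_sigs, epithelial_start):
        spec = self._base_spec(demo, demo_sigs, epithelial_start)
        grid = run_grid(spec, [GridAxis("env", "Hypoxia", (0,))])
        direct = run_experiment(
            dataclasses.replace(
                spec,
                windows=tuple(
                    dataclasses.replace(w, env={**w.env, "Hypoxia": 0})
                    for w in spec.windows
                ),
            )
        )
        merged = grid.merge(
            direct.fractions, on=["window", "module", "phenotype"], suffixes=("_g", "_d")
        )
        assert (merged.fraction_g == merged.fraction_d).all()

    def test_two_axis_grid_collapses_to_series(self, demo, demo_sigs, epithelial_start):
        spec = self._base_spec(demo, demo_sigs, epithelial_start)
        axis1 = GridAxis("env", "Hypoxia", (0, 1))
        axis2 = GridAxis("env", "TGFb_ext", (0,))
        grid2 = run_grid(spec, [axis1, axis2])
        series = run_grid(spec, [axis1])
        collapsed = grid2[grid2.TGFb_ext == 0].drop(columns="TGFb_ext").reset_index(drop=True)
        pd.testing.assert_frame_equal(
            collapsed, series, check_like=True,
        )


class TestCountDivisions:
    def test_periodic_marker_counts_cycles(self):
        # 2-bit counter: period-4 limit cycle, marker ON one phase per cycle
        osc = parse_model("A *= not B\nB *= A")
        sigs = SignatureSet([PhenotypeSignature("M", "mark", {"A": 1, "B": 1})], osc)
        traj = simulate_trajectory(osc, (0, 0), (Window(100, {}),))
        table = count_divisions([traj], sigs.get("M"))
        assert int(table.divisions_mean.iloc[0]) == 25
        assert float(table.cycle_length.iloc[0]) == 4.0

    def test_constant_marker_single_edge(self, emt, emt_sigs):
        sigs = SignatureSet([PhenotypeSignature("M", "mark", {"miR34": 1})], emt)
        traj = simulate_trajectory(emt, emt.state_from({}), (Window(50, {"EMT_signal": 0}),))
        table = count_divisions([traj], sigs.get("M"))
        assert table.divisions_mean.iloc[0] <= 1.0


class TestProtocolFiles:
    YAML = """
name: smoke
model: fixture:hypoxia_demo
signatures: fixture:hypoxia_demo
initial:
  phenotype: Epithelial
  env: {Hypoxia: 0, GF: 1, TGFb_ext: 0, Stiff_ECM: 1, ECM_attached: 1, Density_High: 1}
windows:
  - steps: 10
    env: {Hypoxia: 1, GF: 1, TGFb_ext: 0, Stiff_ECM: 1, ECM_attached: 1, Density_High: 0}
    clamps: [{node: TGFb_secr, mode: off, level: 0.05}]
    noise: 0.02
ensemble: 5
death: Apoptotic
seed: 4
series:
  - {kind: env, node: Hypoxia, levels: [0, 1]}
"""

    def test_load_and_run(self):
        spec, axes = load_protocol(self.YAML)
        assert spec.ensemble == 5 and spec.windows[0].steps == 10
        assert spec.windows[0].clamps["TGFb_secr"].mode == "off"
        assert len(axes) == 1 and axes[0].levels == (0.0, 1.0)
        grid = run_grid(spec, axes)
        assert set(grid.Hypoxia) == {0.0, 1.0}
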