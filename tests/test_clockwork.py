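"""Dual-network clockwork: construction, mean fields, knockdowns, calibration."""

import numpy as np
import pytest

from roachclock import (
    CellSpec,
    ClockworkModel,
    CouplingSpec,
    apply_knockdown,
    build_nominal_clockwork,
    compute_mean_fields,
    make_single_oscillator,
    simulate_clockwork,
    simulate_sls,
)
from roachclock.clockwork import (
    DEFAULT_TAU_LA,
    DEFAULT_TAU_LE,
    LAON,
    LEON,
    calibrate_tau,
    default_calibrated_clockwork,
    scenario_period,
)

ZERO_COUPLING = CouplingSpec(
    E_Le=np.zeros((2, 3)), E_La=np.zeros((2, 3)),
    F_Le=np.zeros((2, 3)), F_La=np.zeros((2, 3)),
)


class TestConstruction:
    def test_nominal_layout(self):
        m = build_nominal_clockwork()
        assert (m.n_Le, m.n_La) == (4, 4)
        assert [c.identity for c in m.cells if c.network == LEON] == ["PER"] * 4
        la_ids = sorted(c.identity for c in m.cells if c.network == LAON)
        assert la_ids == ["PER_CRY2", "PER_CRY2", "TIM1", "TIM1"]
        assert all(c.x0 == (10.0, 10.0, 10.0) for c in m.cells)

    def test_tau_stored_verbatim(self):
        tau_Le = (0.2, 0.21, 0.22, 0.23)
        tau_La = (0.18, 0.19, 0.2, 0.21)
        m = build_nominal_clockwork(tau_Le, tau_La)
        assert m.tau_Le == tau_Le
        assert m.tau_La == tau_La

    def test_printed_coupling_defaults(self):
        c = CouplingSpec()
        np.testing.assert_array_equal(c.E_Le, [[0.07, 0, 0], [-0.07, 0, 0]])
        np.testing.assert_array_equal(c.E_La, [[0.07, 0, 0], [0.07, 0, 0]])
        np.testing.assert_array_equal(c.F_Le, [[-0.05, 0, 0], [0.05, 0, 0]])
        np.testing.assert_array_equal(c.F_La, [[-0.12, 0, 0], [-0.12, 0, 0]])
        assert c.output_weights == (0.5, 0.5)

    def test_nonpositive_tau_rejected(self):
        with pytest.raises(ValueError):
            build_nominal_clockwork((0.0, 1, 1, 1), (1, 1, 1, 1))

    def test_network_identity_constraints(self):
        with pytest.raises(ValueError):
            CellSpec(0, LEON, "TIM1", 1.0)
        with pytest.raises(ValueError):
            CellSpec(0, LAON, "PER", 1.0)


class TestMeanFields:
    def test_constant_thirds(self):
        k_le, k_la, k = compute_mean_fields(np.full(8, 7.0), [LEON] * 4 + [LAON] * 4)
        assert (k_le, k_la, k) == (7.0, 7.0, 7.0)

    def test_arithmetic_example(self):
        thirds = np.array([1.0, 2, 3, 4, 5, 6, 7, 8])
        k_le, k_la, k = compute_mean_fields(thirds, [LEON] * 4 + [LAON] * 4)
        assert (k_le, k_la, k) == (2.5, 6.5, 4.5)

    def test_mean_over_live_cells_only(self):
        k_le, k_la, k = compute_mean_fields(
            np.array([1.0, 2, 3, 4, 5, 7]), [LEON] * 4 + [LAON] * 2
        )
        assert k_la == 6.0

    def test_empty_referenced_network_rejected(self):
        with pytest.raises(ValueError, match="no live cells"):
            compute_mean_fields(np.array([1.0, 2.0]), [LEON, LEON])

    def test_vectorized_over_time(self):
        thirds = np.tile(np.arange(1.0, 9.0), (5, 1))
        k_le, k_la, k = compute_mean_fields(thirds, [LEON] * 4 + [LAON] * 4)
        assert k.shape == (5,)
        np.testing.assert_allclose(k, 4.5)


class TestSimulation:
    def test_decoupled_cells_reduce_to_single_oscillator(self):
        m = build_nominal_clockwork(coupling=ZERO_COUPLING)
        traj = simulate_clockwork(m, duration=100.0, sample_step=0.02)
        single = simulate_sls(make_single_oscillator(), 100.0, sample_step=0.02)
        for j in range(8):
            np.testing.assert_allclose(traj.states[:, j, :], single.states, atol=1e-3)

    def test_decoupled_tau_rescaling(self):
        m = build_nominal_clockwork([2.0] * 4, [2.0] * 4, coupling=ZERO_COUPLING)
        traj = simulate_clockwork(m, duration=50.0, sample_step=0.01)
        single = simulate_sls(make_single_oscillator(tau=2.0), 50.0, sample_step=0.01)
        np.testing.assert_allclose(traj.states[:, 0, :], single.states, atol=1e-3)

    def test_symmetry_oracle_two_cell_representative(self):
        """Uniform networks equal a 2-cell model with one representative per network."""
        m8 = build_nominal_clockwork([0.19] * 4, [0.2] * 4)
        cells2 = (
            CellSpec(0, LEON, "PER", 0.19),
            CellSpec(1, LAON, "TIM1", 0.2),
        )
        m2 = ClockworkModel(cells=cells2)
        # identical cells share one trajectory until roundoff seeds the (transversely
        # unstable) symmetry-breaking mode, which amplifies beyond ~180 h
        t8 = simulate_clockwork(m8, duration=150.0, sample_step=0.02)
        t2 = simulate_clockwork(m2, duration=150.0, sample_step=0.02)
        np.testing.assert_allclose(t8.K, t2.K, atol=1e-6)

    def test_mean_field_definition_holds_along_trajectory(self):
        m = default_calibrated_clockwork()
        traj = simulate_clockwork(m, duration=60.0, sample_step=0.05)
        np.testing.assert_allclose(traj.K_Le, traj.states[:, :4, 2].mean(axis=1), atol=1e-12)
        np.testing.assert_allclose(traj.K, 0.5 * (traj.K_Le + traj.K_La), atol=1e-12)

    def test_calibrated_model_synchronizes(self):
        m = default_calibrated_clockwork()
        traj = simulate_clockwork(m, duration=600.0, sample_step=0.02)
        from roachclock import estimate_period_peaks

        periods = [
            estimate_period_peaks(traj.states[:, j, 2], 0.02, transient_discard=200).period
            for j in range(8)
        ]
        assert max(periods) - min(periods) < 0.1
        k_est = estimate_period_peaks(traj.K, 0.02, transient_discard=200)
        assert k_est.dispersion < 0.02


class TestKnockdowns:
    @pytest.mark.parametrize(
        "gene, n_le, n_la, surviving_la",
        [
            ("PER", 1, 2, {"TIM1"}),
            ("TIM1", 4, 2, {"PER_CRY2"}),
            ("CRY2", 4, 2, {"TIM1"}),
        ],
    )
    def test_elimination_counts(self, gene, n_le, n_la, surviving_la):
        m = apply_knockdown(build_nominal_clockwork(), gene)
        assert (m.n_Le, m.n_La) == (n_le, n_la)
        assert {c.identity for c in m.cells if c.network == LAON} == surviving_la

    def test_survivors_keep_tau(self):
        tau_Le = (0.2, 0.21, 0.22, 0.23)
        tau_La = (0.18, 0.19, 0.2, 0.21)
        m = apply_knockdown(build_nominal_clockwork(tau_Le, tau_La), "PER", per_survivor=2)
        assert m.tau_Le == (0.22,)
        assert m.tau_La == (0.18, 0.19)

    def test_unknown_gene_rejected(self):
        with pytest.raises(ValueError, match="unknown knockdown gene"):
            apply_knockdown(build_nominal_clockwork(), "CLOCK")

    def test_non_nominal_layout_rejected(self):
        reduced = apply_knockdown(build_nominal_clockwork(), "TIM1")
        with pytest.raises(ValueError, match="nominal"):
            apply_knockdown(reduced, "PER")

    def test_mirrored_pairs_make_laon_knockdowns_exact_no_ops(self):
        """Removing one cell of each identical LaON pair cannot change K(t)."""
        m = build_nominal_clockwork([0.19, 0.2, 0.19, 0.2], [0.21, 0.18, 0.21, 0.18])
        # compare before roundoff-seeded symmetry breaking amplifies (~180 h)
        nominal = simulate_clockwork(m, duration=150.0, sample_step=0.05)
        for gene in ("TIM1", "CRY2"):
            kd = simulate_clockwork(apply_knockdown(m, gene), duration=150.0, sample_step=0.05)
            np.testing.assert_allclose(kd.K, nominal.K, atol=1e-6)


class TestCalibration:
    def test_round_trip_recovers_generated_targets(self):
        """Calibrating against periods simulated from a known tau set reproduces them."""
        from roachclock.synth import generate_clockwork_targets

        true_tau = np.array([0.186, 0.184, 0.184, 0.184, 0.205, 0.205, 0.194, 0.194])
        targets = generate_clockwork_targets(
            true_tau[:4], true_tau[4:], scenarios=("nominal", "PER"),
            duration=400.0, transient=200.0, sample_step=0.05,
        )
        res = calibrate_tau(
            targets,
            parameterization="clustered",
            tolerance=0.05,
            duration=400.0,
            transient=200.0,
            sample_step=0.05,
            initial_guess=true_tau[[0, 1, 4, 6]] * 1.01,
            max_evaluations=60,
            sync_weight=0.0,
            order_weight=0.0,
            raise_on_failure=False,
        )
        assert res.max_abs_residual < 0.05

    def test_mirrored_scheme_rejects_knockdown_separation(self):
        """Mirrored pairs cannot separate the LaON knockdowns from nominal."""
        res = calibrate_tau(
            {"nominal": 23.6, "TIM1": 20.5},
            parameterization="mirrored-pair",
            duration=300.0,
            transient=150.0,
            sample_step=0.05,
            max_evaluations=25,
            raise_on_failure=False,
        )
        # achieved TIM1 equals achieved nominal no matter what the optimizer does
        assert abs(res.achieved["TIM1"] - res.achieved["nominal"]) < 0.02
        assert not res.converged

    def test_leading_network_alone_runs_faster_than_24h(self):
        """The calibrated LeON by itself (cross-coupling removed) leads (< 24 h)."""
        no_cross = CouplingSpec(F_Le=np.zeros((2, 3)), F_La=np.zeros((2, 3)),
                                output_weights=(1.0, 0.0))
        cells = tuple(CellSpec(j, LEON, "PER", t) for j, t in enumerate(DEFAULT_TAU_LE))
        m = ClockworkModel(cells=cells, coupling=no_cross)
        est = scenario_period(m, duration=400.0, transient=200.0, sample_step=0.05)
        assert est.period < 24.0

    def test_invalid_targets_rejected(self):
        with pytest.raises(ValueError):
            calibrate_tau({"BMAL1": 24.0})
        with pytest.raises(ValueError):
            calibrate_tau({})
        with pytest.raises(ValueError):
            calibrate_tau({"nominal": -1.0})
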