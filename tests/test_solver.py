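"""Coupled-system assembly, current bookkeeping, and the integrators."""

import numpy as np
import pytest

import ephapsim as ep
from ephapsim.errors import ValidationError
from ephapsim.solver import ephaptic_currents, membrane_currents


def pair_system(sigma=0.05, nseg=9, length=400.0, amp=0.4, mode="closed_loop",
                formulation="eliminated_ode", rel_tol=1e-6, abs_tol=1e-8):
    net = ep.fixture_network("pair", nseg=nseg, length=length)
    opts = ep.SolverOptions(mode=mode, formulation=formulation,
                            rel_tol=rel_tol, abs_tol=abs_tol)
    stim = ep.StimulusSpec(target=0, waveform="dc", amplitude=amp)
    return ep.assemble(net, {"hh": ep.hh_model()}, [stim],
                       medium=ep.ExtracellularMedium(sigma), options=opts)


class TestAssemble:
    def test_single_passive_compartment_layout(self, single_sphere_net):
        net = single_sphere_net("pas")
        sys_ = ep.assemble(net, {"pas": ep.passive_model()},
                           options=ep.SolverOptions(mode="open_loop"))
        assert sys_.n_states == 1
        assert sys_.axial.nnz == 1 and sys_.axial[0, 0] == 0.0

    def test_ball_and_stick_axial_topology(self):
        net = ep.fixture_network("ball_and_stick", nseg=5)
        sys_ = ep.assemble(net, {"hh": ep.hh_model()},
                           options=ep.SolverOptions(mode="open_loop"))
        assert sys_.n == 6
        off_diag = sys_.axial.toarray().copy()
        np.fill_diagonal(off_diag, 0.0)
        assert (off_diag > 0).sum() == 2 * 5  # 5 symmetric couplings

    def test_axial_matrix_rows_sum_to_zero(self):
        net = ep.fixture_network("branched", nseg=7)
        sys_ = ep.assemble(net, {"hh": ep.hh_model()},
                           options=ep.SolverOptions(mode="open_loop"))
        assert np.max(np.abs(sys_.axial.sum(axis=1))) < 1e-12
        a = sys_.axial.toarray()
        assert np.max(np.abs(a - a.T)) < 1e-12

    def test_unbound_segment_named_in_error(self, single_sphere_net):
        net = single_sphere_net("mystery_model")
        with pytest.raises(ValidationError, match="mystery_model"):
            ep.assemble(net, {"hh": ep.hh_model()},
                        options=ep.SolverOptions(mode="open_loop"))

    def test_closed_loop_without_medium_rejected(self, single_sphere_net):
        net = single_sphere_net("pas")
        with pytest.raises(ValidationError):
            ep.assemble(net, {"pas": ep.passive_model()},
                        options=ep.SolverOptions(mode="closed_loop"))


class TestCurrentBookkeeping:
    def test_equilibrium_has_zero_membrane_currents(self):
        net = ep.fixture_network("axon", nseg=5)
        pas = ep.passive_model(g_leak=0.3, e_leak=-65.0)
        for s in net.segments:
            s.model_tag = "pas"
        sys_ = ep.assemble(net, {"pas": pas},
                           options=ep.SolverOptions(mode="open_loop"))
        x = sys_.initial_state()
        assert np.max(np.abs(membrane_currents(sys_, 0.0, x))) < 1e-12

    def test_membrane_equals_axial_bookkeeping(self, hh, axon_net):
        stim = ep.StimulusSpec(target=0, waveform="dc", amplitude=0.5)
        sys_ = ep.assemble(axon_net, {"hh": hh}, [stim],
                           options=ep.SolverOptions(mode="open_loop"))
        res = ep.solve(sys_, (0.0, 5.0))
        k = 120  # mid-spike sample
        x = np.concatenate([
            res.vm[:, k],
            np.concatenate([res.gating[f"hh.{nm}"][:, k]
                            for nm in ("m", "h", "n")])])
        t = res.times[k]
        i_axial = membrane_currents(sys_, t, x)
        # membrane side: C dVm/dt + I_ion * area (no synapses here)
        dx = sys_.rhs(t, x, "open_loop")
        vm, gating, _ = sys_.unpack(x)
        i_ion, _ = sys_._ionic(t, vm, gating)
        i_mem = sys_.capacitance * dx[:sys_.n] + i_ion
        assert np.max(np.abs(i_axial - i_mem)) < 1e-9

    def test_per_cell_current_conservation(self, hh):
        sys_ = pair_system(mode="open_loop")
        res = ep.solve(sys_, (0.0, 10.0))
        for k in (40, 200, 399):
            x = np.concatenate([
                res.vm[:, k],
                np.concatenate([res.gating[f"hh.{nm}"][:, k]
                                for nm in ("m", "h", "n")])])
            im = membrane_currents(sys_, res.times[k], x)
            inj = sys_.injected_currents(res.times[k], x)
            for ci in (0, 1):
                cell = sys_.cell_index == ci
                assert np.sum(im[cell]) == pytest.approx(
                    np.sum(inj[cell]), abs=1e-9)

    def test_two_compartment_steady_state_matches_circuit_solution(self):
        # two passive spheres joined by a known resistance, DC into node 0;
        # oracle: direct 2x2 nodal analysis
        cell = ep.Cell("c")
        cell.add_section(ep.sphere("a", 10.0, model_tag="pas"))
        cell.add_section(ep.cylinder("link", 1.0, 50.0,
                                     proximal_point=(10.0, 0, 0),
                                     model_tag="pas"))
        ep.connect(cell, "link", 0, "a", 1)
        net = ep.discretize(ep.Network().add(cell))
        pas = ep.passive_model(g_leak=0.3, e_leak=-65.0)
        i0 = 0.05
        sys_ = ep.assemble(net, {"pas": pas},
                           [ep.StimulusSpec(target=0, waveform="dc",
                                            amplitude=i0)],
                           options=ep.SolverOptions(mode="open_loop"))
        res = ep.solve(sys_, (0.0, 60.0))
        g = np.array([0.3 * s.area * 1e-5 for s in net.segments])
        r_link = net.segments[0].neighbors[0][1]
        G = np.array([[g[0] + 1 / r_link, -1 / r_link],
                      [-1 / r_link, g[1] + 1 / r_link]])
        v_ss = np.linalg.solve(G, np.array([i0 + g[0] * -65.0,
                                            g[1] * -65.0]))
        assert res.vm[:, -1] == pytest.approx(v_ss, rel=5e-3)
        # steady-state membrane current split: all injected current leaves
        # through the leaks in proportion to the nodal solution
        x = np.concatenate([res.vm[:, -1], np.zeros(0)])
        im = membrane_currents(sys_, res.times[-1], x)
        i_leak = g * (v_ss + 65.0)
        assert im == pytest.approx(i_leak, rel=5e-3)


class TestEphapticCurrents:
    def test_uniform_vout_gives_zero(self):
        sys_ = pair_system(mode="open_loop")
        i = ephaptic_currents(sys_, np.full(sys_.n, 3.7))
        assert np.max(np.abs(i)) < 1e-12

    def test_three_segment_hand_value(self):
        # Vout = (1, 0, 0) mV across 10-Mohm links: i_eph = (-0.1, .1, 0) nA
        cell = ep.Cell("c").add_section(
            ep.cylinder("a", 1.0, 3 * 10 * np.pi, nseg=3, ra=1000.0 / 3))
        net = ep.discretize(ep.Network().add(cell))
        r = net.segments[0].neighbors[0][1]
        sys_ = ep.assemble(net, {"hh": ep.hh_model()},
                           options=ep.SolverOptions(mode="open_loop"))
        i = ephaptic_currents(sys_, np.array([1.0, 0.0, 0.0]))
        assert i == pytest.approx([-1.0 / r, 1.0 / r, 0.0], rel=1e-12)

    def test_telescoping_sum_leaves_boundary_terms(self):
        sys_ = pair_system(mode="open_loop")
        vout = np.sin(np.arange(sys_.n) * 0.3)
        i = ephaptic_currents(sys_, vout)
        for ci in (0, 1):
            assert np.sum(i[sys_.cell_index == ci]) == pytest.approx(
                0.0, abs=1e-12)


class TestClosedLoop:
    def test_self_consistency_at_every_stored_time(self):
        sys_ = pair_system()
        res = ep.solve(sys_, (0.0, 10.0))
        resid = res.vout - sys_.transfer.entries @ res.membrane_currents
        assert np.max(np.abs(resid)) < 10 * sys_.options.abs_tol + 1e-12

    def test_driven_axon_deflects_silent_neighbor(self):
        sys_ = pair_system(sigma=0.05)
        res = ep.solve(sys_, (0.0, 30.0))
        n = sys_.n // 2
        driven_spikes = ep.detect_spikes(res.times, res.vm[0])
        assert len(driven_spikes.times) >= 2
        deflection = np.ptp(res.vm[n:], axis=1).max()
        assert 0.01 < deflection < 10.0  # subthreshold but visible
        # deflections are time-locked: neighbor departs from rest only once
        # the driven axon starts spiking
        neigh = res.vm[n]
        t_move = res.times[np.argmax(np.abs(neigh - neigh[0]) > 0.005)]
        assert abs(t_move - driven_spikes.times[0]) < 5.0

    def test_quiescent_network_stays_constant(self):
        net = ep.fixture_network("pair", nseg=5)
        pas = ep.passive_model(g_leak=0.0, e_leak=-65.0)
        for s in net.segments:
            s.model_tag = "pas"
        sys_ = ep.assemble(net, {"pas": pas},
                           medium=ep.ExtracellularMedium(0.3),
                           options=ep.SolverOptions(mode="closed_loop"))
        res = ep.solve(sys_, (0.0, 20.0), x0=sys_.initial_state(vm0=-65.0))
        assert np.max(np.abs(res.vm + 65.0)) < 1e-9
        assert np.max(np.abs(res.vout)) < 1e-9

    def test_formulations_agree_subthreshold(self):
        kw = dict(sigma=0.05, amp=0.05, rel_tol=1e-8, abs_tol=1e-10)
        r1 = ep.solve(pair_system(formulation="eliminated_ode", **kw),
                      (0.0, 20.0))
        r2 = ep.solve(pair_system(formulation="mass_matrix_dae", **kw),
                      (0.0, 20.0))
        scale = np.max(np.abs(r1.vm))
        assert np.max(np.abs(r1.vm - r2.vm)) < 10 * (1e-8 * scale + 1e-10)


class TestOpenLoop:
    def test_spike_propagates_in_segment_order(self, hh, axon_net):
        stim = ep.StimulusSpec(target=0, waveform="dc", amplitude=0.5)
        sys_ = ep.assemble(axon_net, {"hh": hh}, [stim],
                           options=ep.SolverOptions(mode="open_loop"))
        res = ep.solve(sys_, (0.0, 30.0))
        first = [ep.detect_spikes(res.times, res.vm[k]).times[0]
                 for k in (0, 10, 20, 30, 40)]
        assert all(a < b for a, b in zip(first, first[1:]))
        assert len(ep.detect_spikes(res.times, res.vm[40]).times) >= 2

    def test_high_sigma_closed_loop_approaches_open_loop(self):
        kw = dict(rel_tol=1e-8, abs_tol=1e-10)
        reso = ep.solve(pair_system(mode="open_loop", **kw), (0.0, 20.0))
        diffs = []
        for sigma in (0.05, 0.5, 5.0, 50.0):
            resc = ep.solve(pair_system(sigma=sigma, **kw), (0.0, 20.0))
            diffs.append(np.max(np.abs(resc.vm - reso.vm)))
        assert all(a >= b for a, b in zip(diffs, diffs[1:]))
        assert diffs[-1] < 0.05


class TestReferenceSolve:
    def test_linear_system_matches_exact_exponential(self, single_sphere_net):
        net = single_sphere_net("pas")
        pas = ep.passive_model(g_leak=0.3, e_leak=-65.0)
        sys_ = ep.assemble(net, {"pas": pas},
                           options=ep.SolverOptions(mode="open_loop"))
        x0 = sys_.initial_state(vm0=-55.0)
        dt = 0.005
        ref = ep.reference_solve(sys_, (0.0, 5.0), dt, x0=x0)
        tau = 1.0 / 0.3
        exact = -65.0 + 10.0 * np.exp(-ref.times / tau)
        err = np.max(np.abs(ref.vm[0] - exact))
        assert err < 5 * dt  # first-order accuracy
        ref2 = ep.reference_solve(sys_, (0.0, 5.0), dt / 5, x0=x0)
        err2 = np.max(np.abs(ref2.vm[0] - exact))
        assert err2 < err / 3  # O(dt) convergence

    def test_monotone_convergence_to_adaptive_solution(self, hh):
        net = ep.fixture_network("axon", nseg=11, length=300.0)
        stim = ep.StimulusSpec(target=0, waveform="dc", amplitude=0.3)
        sys_ = ep.assemble(net, {"hh": hh}, [stim],
                           options=ep.SolverOptions(mode="open_loop",
                                                    rel_tol=1e-8,
                                                    abs_tol=1e-10))
        res = ep.solve(sys_, (0.0, 8.0))
        errs = []
        for dt in (0.005, 0.0025, 0.00125):
            ref = ep.reference_solve(sys_, (0.0, 8.0), dt)
            errs.append(np.max(np.abs(ref.vm - res.vm)))
        assert errs[0] > errs[1] > errs[2]

    def test_bit_identical_repeat_runs(self):
        sys_ = pair_system(mode="open_loop", nseg=5, length=200.0)
        r1 = ep.reference_solve(sys_, (0.0, 2.0), 0.005)
        r2 = ep.reference_solve(sys_, (0.0, 2.0), 0.005)
        assert np.array_equal(r1.vm, r2.vm)
        assert np.array_equal(r1.vout, r2.vout)


class TestLimitCycleInit:
    def test_seeded_phases_reproducible_and_seed_dependent(self, hh):
        net = ep.fixture_network("pair", nseg=7, length=300.0)
        stims = [ep.StimulusSpec(target=0, waveform="dc", amplitude=0.4),
                 ep.StimulusSpec(target=7, waveform="dc", amplitude=0.45)]
        sys_ = ep.assemble(net, {"hh": hh}, stims,
                           options=ep.SolverOptions(mode="open_loop"))
        a = ep.randomized_limit_cycle_init(
            sys_, np.random.default_rng(5), settle_ms=120.0)
        b = ep.randomized_limit_cycle_init(
            sys_, np.random.default_rng(5), settle_ms=120.0)
        c = ep.randomized_limit_cycle_init(
            sys_, np.random.default_rng(6), settle_ms=120.0)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)
        # sampled states lie in the physiological range
        assert np.all(a[:sys_.n] > -90) and np.all(a[:sys_.n] < 60)
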