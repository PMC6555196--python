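"""Assembly and integration of the coupled membrane/extracellular system.

Per segment i the cable balance reads (units: nA, mV, ms, Mohm)

    C_i dVm_i/dt + I_ion_i * area_i
        = sum_j (Vin_j - Vin_i) / R_ij + I_inj_i + I_gap_i + I_syn_i

with Vin = Vm + Vout.  Splitting the axial term gives the usual cable
equation plus the *ephaptic current*

    i_eph_i = sum_j (Vout_j - Vout_i) / R_ij ,

the extra axial drive produced by gradients of the extracellular potential.
Vout itself is generated by the network's membrane currents through the
transfer matrix, Vout = T @ I_m (plus any extracellular stimulus), and I_m
depends on Vout again — an algebraic loop that must hold self-consistently
at every instant.

Two closed-loop formulations are provided:

``eliminated_ode`` (default)
    The algebraic constraint is linear in Vout, so it is solved exactly
    inside every derivative evaluation:

        (Id - T A) Vout = T ((A + G) Vm + I_inj) + V_stim

    with A the axial conductance Laplacian and G the gap-junction coupling.
    The result is an ordinary (stiff) ODE in (Vm, gating, synapse) states,
    mathematically identical to the singular-mass-matrix DAE.

``mass_matrix_dae``
    Vout is kept as an explicit block of the state vector (the algebraic
    variables of the DAE M x' = f with zeros on M's diagonal).  Because the
    constraint is linear, one differentiation (index reduction) turns it
    into an ODE for Vout that is integrated alongside the membrane states,
    starting from a consistent initialization.  This is a genuinely
    different code path used to cross-check the default formulation.

``reference_solve`` is an independent fixed-step backward-Euler/Newton
integrator sharing no time-stepping machinery with the adaptive path; it
plays the role of an external oracle in the validation suite.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field as dc_field

import numpy as np
import scipy.sparse as sp
from scipy.integrate import solve_ivp
from scipy.linalg import lu_factor, lu_solve

from .dynamics import (MembraneModel, StimulusSpec, SynapseSpec,
                       biexp_normalization, stimulus_current)
from .errors import ConditioningError, SolverError, ValidationError
from .field import (ExtracellularMedium, SamplingSpec, TransferMatrix,
                    build_transfer_matrix, extracellular_pattern,
                    segment_sample_points)
from .morphology import Network
from .units import MA_CM2_UM2_TO_NA, NS_MV_TO_NA, UF_CM2_UM2_TO_NF

__all__ = [
    "SolverOptions",
    "CoupledSystem",
    "SimulationResult",
    "assemble",
    "membrane_currents",
    "ephaptic_currents",
    "solve_closed_loop",
    "solve_open_loop",
    "solve",
    "reference_solve",
    "randomized_limit_cycle_init",
]


@dataclass
class SolverOptions:
    """Integrator configuration.

    Defaults are deliberately tight (rel_tol 1e-6, abs_tol 1e-8 mV) because
    spike-timing comparisons at the tens-of-microseconds level require them;
    dense output is sampled every 0.025 ms.
    """

    rel_tol: float = 1e-6
    abs_tol: float = 1e-8
    max_step: float = np.inf
    mode: str = "closed_loop"
    formulation: str = "eliminated_ode"
    seed: int = 0
    dense_output_dt: float = 0.025
    settle_time: float = 500.0  # ms, for limit-cycle initialization

    def __post_init__(self):
        if self.rel_tol <= 0 or self.abs_tol <= 0:
            raise ValidationError("tolerances must be > 0")
        if self.dense_output_dt <= 0:
            raise ValidationError("dense_output_dt must be > 0")
        if self.mode not in ("closed_loop", "open_loop"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if self.formulation not in ("eliminated_ode", "mass_matrix_dae"):
            raise ValidationError(f"unknown formulation {self.formulation!r}")


class _StateView:
    """What a custom (autonomous) stimulus sees of the current state."""

    __slots__ = ("t", "vm", "x")

    def __init__(self, t, vm, x):
        self.t, self.vm, self.x = t, vm, x


@dataclass
class SimulationResult:
    """Time series on a uniform dense-output grid.

    vm, vout, membrane_currents: (n_segments, n_times) in mV / mV / nA;
    gating: dict of state name -> (n_segments_of_group, n_times) with the
    owning segment ids in ``gating_segments``.
    """

    times: np.ndarray
    vm: np.ndarray
    vout: np.ndarray
    gating: dict[str, np.ndarray]
    gating_segments: dict[str, np.ndarray]
    membrane_currents: np.ndarray
    metadata: dict = dc_field(default_factory=dict)


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

@dataclass
class _ModelGroup:
    tag: str
    model: MembraneModel
    seg_idx: np.ndarray            # segment ids bound to this model
    state_slice: slice             # rows in the packed state vector


class CoupledSystem:
    """Assembled network + dynamics + field, ready to integrate."""

    def __init__(self, network: Network, models: dict[str, MembraneModel],
                 stimuli, synapses, medium, options: SolverOptions,
                 sampling: SamplingSpec | None = None):
        self.network = network
        self.models = models
        self.stimuli = list(stimuli)
        self.synapses = list(synapses)
        self.medium = medium
        self.options = options
        self.sampling = sampling or SamplingSpec()

        segs = network.segments
        if not segs:
            raise ValidationError("network is not discretized")
        n = len(segs)
        self.n = n
        self.areas = np.array([s.area for s in segs])
        self.capacitance = np.array(
            [s.cm * s.area * UF_CM2_UM2_TO_NF for s in segs])  # nF
        self.cell_index = np.array([s.cell_index for s in segs])

        # axial conductance Laplacian (uS); symmetric, zero row sums per cell
        rows, cols, vals = [], [], []
        for s in segs:
            for j, r in s.neighbors:
                rows.append(s.id)
                cols.append(j)
                vals.append(1.0 / r)
        diag = np.zeros(n)
        for i, v in zip(rows, vals):
            diag[i] -= v
        self.axial = sp.csr_matrix(
            (vals + list(diag), (rows + list(range(n)),
                                 cols + list(range(n)))), shape=(n, n))

        # gap-junction coupling Laplacian (uS)
        g_rows, g_cols, g_vals = [], [], []
        for syn in self.synapses:
            if syn.kind != "gap":
                continue
            g = syn.g_max * NS_MV_TO_NA  # nS -> uS
            a, b = int(syn.pre), int(syn.post)
            g_rows += [a, b, a, b]
            g_cols += [b, a, a, b]
            g_vals += [g, g, -g, -g]
        self.gap = sp.csr_matrix((g_vals, (g_rows, g_cols)), shape=(n, n))

        # model groups and state layout
        tags = [s.model_tag for s in segs]
        for tag in tags:
            if tag not in models:
                seg_id = tags.index(tag)
                raise ValidationError(
                    f"segment {seg_id} is bound to unknown model {tag!r}")
        self.groups: list[_ModelGroup] = []
        offset = n
        for tag in dict.fromkeys(tags):  # stable unique order
            model = models[tag]
            idx = np.array([i for i, t in enumerate(tags) if t == tag])
            width = model.n_states * len(idx)
            self.groups.append(_ModelGroup(
                tag, model, idx, slice(offset, offset + width)))
            offset += width
        self.syn_specs = [s for s in self.synapses if s.kind != "gap"]
        self.syn_slice = slice(offset, offset + 2 * len(self.syn_specs))
        offset += 2 * len(self.syn_specs)
        self.n_states = offset

        self._intra = [s for s in self.stimuli if s.side == "intracellular"]
        self._extra = [s for s in self.stimuli if s.side == "extracellular"]
        self._has_custom_state = any(
            s.waveform == "custom" for s in self.stimuli)

        # extracellular stimulus patterns, boundary-averaged per segment
        self._extra_patterns = []
        if self._extra:
            if medium is None:
                raise ValidationError(
                    "extracellular stimulation requires a medium")
            for spec in self._extra:
                vals_per_seg = np.empty(n)
                for i, seg in enumerate(segs):
                    pts = segment_sample_points(seg, self.sampling, network)
                    vals_per_seg[i] = float(np.mean(
                        extracellular_pattern(spec, pts, medium)))
                self._extra_patterns.append(vals_per_seg)

        # closed-loop linear elimination operators
        self.transfer: TransferMatrix | None = None
        self._lu = None
        self._S = None   # Vout = S @ Vm + P @ I_inj (+ Q @ V_stim)
        self._P = None
        self._Q = None
        if options.mode == "closed_loop":
            if medium is None:
                raise ValidationError("closed loop requires a medium")
            self._build_closed_loop_operators()

    # -- operators -----------------------------------------------------

    def _build_closed_loop_operators(self):
        self.transfer = build_transfer_matrix(
            self.network, self.medium, self.sampling)
        T = self.transfer.entries
        A = self.axial.toarray()
        M = np.eye(self.n) - T @ A
        try:
            self._lu = lu_factor(M)
        except Exception as exc:  # pragma: no cover - defensive
            raise ConditioningError(
                f"closed-loop system singular at sigma = "
                f"{self.medium.sigma} S/m") from exc
        cond_proxy = np.abs(np.diag(self._lu[0])).min()
        if cond_proxy < 1e-12:
            raise ConditioningError(
                f"(Id - T A) is numerically singular at sigma = "
                f"{self.medium.sigma} S/m (geometry scale "
                f"{np.ptp(self.network.segment_centers()):.3g} um)")
        AG = (self.axial + self.gap).toarray()
        self._S = lu_solve(self._lu, T @ AG)
        self._P = lu_solve(self._lu, T)
        if self._extra:
            self._Q = lu_solve(self._lu, np.eye(self.n))
        # precomputed dense Vm-coupling for rhs/jacobian
        self._lin_vm_closed = AG + A @ self._S

    def ensure_transfer(self):
        """Build the transfer matrix lazily (open-loop post-hoc use)."""
        if self.transfer is None:
            if self.medium is None:
                raise ValidationError("no medium to build a transfer matrix")
            self.transfer = build_transfer_matrix(
                self.network, self.medium, self.sampling)
        return self.transfer

    # -- state packing -------------------------------------------------

    def unpack(self, x):
        vm = x[:self.n]
        gating = {g.tag: x[g.state_slice].reshape(g.model.n_states,
                                                  len(g.seg_idx))
                  for g in self.groups}
        syn = x[self.syn_slice].reshape(-1, 2)
        return vm, gating, syn

    def initial_state(self, vm0: float | np.ndarray | None = None):
        """Rest state: Vm at each model's resting potential, gating at its
        steady state, synapse states at zero."""
        x = np.zeros(self.n_states)
        for g in self.groups:
            rest = (float(np.mean(np.atleast_1d(vm0)))
                    if vm0 is not None else g.model.resting_potential())
            x[g.seg_idx] = rest
            st = g.model.initial_state(
                np.full(len(g.seg_idx), rest), g.model.params)
            x[g.state_slice] = st.reshape(-1)
        if vm0 is not None and np.ndim(vm0) > 0:
            x[:self.n] = np.asarray(vm0, dtype=float)
        return x

    # -- instantaneous pieces -------------------------------------------

    def injected_currents(self, t, x):
        """Intracellular electrode currents per segment (nA)."""
        out = np.zeros(self.n)
        if not self._intra:
            return out
        view = _StateView(t, x[:self.n], x)
        for spec in self._intra:
            out[spec.target] += stimulus_current(spec, t, view)
        return out

    def stimulus_vout(self, t, x):
        """Imposed extracellular potential per segment (mV)."""
        out = np.zeros(self.n)
        view = _StateView(t, x[:self.n], x)
        for spec, pattern in zip(self._extra, self._extra_patterns):
            out += stimulus_current(spec, t, view) * pattern
        return out

    def _ionic(self, t, vm, gating):
        """Total ionic current (nA, outward) and packed gating derivatives."""
        i_ion = np.zeros(self.n)
        dstate = np.zeros(self.n_states)
        for g in self.groups:
            i_spec, dst = g.model.evaluate(t, vm[g.seg_idx], gating[g.tag],
                                           g.model.params)
            i_ion[g.seg_idx] = i_spec * self.areas[g.seg_idx] * MA_CM2_UM2_TO_NA
            dstate[g.state_slice] = dst.reshape(-1)
        return i_ion, dstate

    def _synaptic(self, vm, syn):
        """Synaptic current (nA, outward) per segment and syn-state derivs."""
        i_syn = np.zeros(self.n)
        dsyn = np.zeros((len(self.syn_specs), 2))
        for k, spec in enumerate(self.syn_specs):
            norm = biexp_normalization(spec.tau_rise, spec.tau_decay)
            g = spec.g_max * norm * (syn[k, 1] - syn[k, 0])  # nS
            i_syn[spec.post] += NS_MV_TO_NA * g * (vm[spec.post] - spec.e_syn)
            dsyn[k, 0] = -syn[k, 0] / spec.tau_rise
            dsyn[k, 1] = -syn[k, 1] / spec.tau_decay
        return i_syn, dsyn

    def vout_of(self, t, x, mode=None):
        """Self-consistent (closed loop) or imposed (open loop) Vout (mV)."""
        mode = mode or self.options.mode
        vm = x[:self.n]
        v_stim = self.stimulus_vout(t, x)
        if mode == "open_loop":
            return v_stim
        i_inj = self.injected_currents(t, x)
        vout = self._S @ vm + self._P @ i_inj
        if self._extra:
            vout += self._Q @ v_stim
        return vout

    # -- right-hand sides -----------------------------------------------

    def rhs(self, t, x, mode=None):
        mode = mode or self.options.mode
        vm, gating, syn = self.unpack(x)
        i_inj = self.injected_currents(t, x)
        i_ion, dx = self._ionic(t, vm, gating)
        i_syn, dsyn = self._synaptic(vm, syn)
        vout = self.vout_of(t, x, mode)
        axial_drive = self.axial @ (vm + vout) + self.gap @ vm
        dvm = (axial_drive + i_inj - i_ion - i_syn) / self.capacitance
        dx[:self.n] = dvm
        dx[self.syn_slice] = dsyn.reshape(-1)
        return dx

    def jac(self, t, x, mode=None):
        """Analytic/semi-analytic Jacobian of :meth:`rhs`.

        Linear parts (axial, gap, ephaptic elimination, synapse decay) are
        exact; the per-segment ionic block is obtained by vectorized finite
        differences on the membrane model (local in each segment, so one
        perturbed evaluation per state variable suffices for the whole
        network).  Returns a sparse matrix in open loop, dense in closed
        loop.  ``None`` is returned when a state-dependent custom stimulus
        makes the structure unknown.
        """
        if self._has_custom_state:
            return None
        mode = mode or self.options.mode
        n, ns = self.n, self.n_states
        vm, gating, syn = self.unpack(x)
        dense = mode == "closed_loop"
        if dense:
            J = np.zeros((ns, ns))
            J[:n, :n] = self._lin_vm_closed / self.capacitance[:, None]
        else:
            J = np.zeros((ns, ns))
            J[:n, :n] = (self.axial + self.gap).toarray() \
                / self.capacitance[:, None]

        eps = 1e-6
        for g in self.groups:
            idx = g.seg_idx
            st = gating[g.tag]
            i0, d0 = g.model.evaluate(t, vm[idx], st, g.model.params)
            # d(i_ion)/dVm and d(dstate)/dVm (both diagonal in the segment)
            i1, d1 = g.model.evaluate(t, vm[idx] + eps, st, g.model.params)
            di_dv = (i1 - i0) / eps * self.areas[idx] * MA_CM2_UM2_TO_NA
            J[idx, idx] -= di_dv / self.capacitance[idx]
            nst = g.model.n_states
            # rows are laid out state-major (state s block over idx)
            for s in range(nst):
                r = g.state_slice.start + s * len(idx) + np.arange(len(idx))
                J[r, idx] = (d1[s] - d0[s]) / eps
            for s in range(nst):
                stp = st.copy()
                stp[s] += eps
                i2, d2 = g.model.evaluate(t, vm[idx], stp, g.model.params)
                di_ds = (i2 - i0) / eps * self.areas[idx] * MA_CM2_UM2_TO_NA
                cols = g.state_slice.start + s * len(idx) + np.arange(len(idx))
                J[idx, cols] -= di_ds / self.capacitance[idx]
                for s2 in range(nst):
                    r = g.state_slice.start + s2 * len(idx) + np.arange(len(idx))
                    J[r, cols] += (d2[s2] - d0[s2]) / eps
        # synapses
        for k, spec in enumerate(self.syn_specs):
            norm = biexp_normalization(spec.tau_rise, spec.tau_decay)
            base = self.syn_slice.start + 2 * k
            gcond = spec.g_max * norm * (syn[k, 1] - syn[k, 0])
            p = spec.post
            J[p, p] -= NS_MV_TO_NA * gcond / self.capacitance[p]
            drive = NS_MV_TO_NA * spec.g_max * norm * (vm[p] - spec.e_syn)
            J[p, base] += drive / self.capacitance[p]       # d/ds_rise (-g)
            J[p, base + 1] -= drive / self.capacitance[p]   # d/ds_decay (+g)
            J[base, base] = -1.0 / spec.tau_rise
            J[base + 1, base + 1] = -1.0 / spec.tau_decay
        return J if dense else sp.csc_matrix(J)

    # -- DAE (index-reduced mass-matrix) form ---------------------------

    def dae_rhs(self, t, z):
        """RHS of the augmented system [x; Vout] (see module docstring)."""
        x, vout = z[:self.n_states], z[self.n_states:]
        vm, gating, syn = self.unpack(x)
        i_inj = self.injected_currents(t, x)
        i_ion, dx = self._ionic(t, vm, gating)
        i_syn, dsyn = self._synaptic(vm, syn)
        dvm = (self.axial @ (vm + vout) + self.gap @ vm
               + i_inj - i_ion - i_syn) / self.capacitance
        dx[:self.n] = dvm
        dx[self.syn_slice] = dsyn.reshape(-1)
        # differentiated constraint: (Id - T A) dVout = T((A+G) dVm + dI/dt)
        #                                             + dV_stim/dt
        di_inj = self._stim_time_derivative(t, x, intracellular=True)
        dv_stim = self._stim_time_derivative(t, x, intracellular=False)
        rhs = self.transfer.entries @ (
            (self.axial + self.gap) @ dvm + di_inj) + dv_stim
        dvout = lu_solve(self._lu, rhs)
        return np.concatenate([dx, dvout])

    def _stim_time_derivative(self, t, x, intracellular: bool):
        out = np.zeros(self.n)
        specs = self._intra if intracellular else self._extra
        patterns = None if intracellular else self._extra_patterns
        view = _StateView(t, x[:self.n], x)
        for k, spec in enumerate(specs):
            if spec.waveform == "dc":
                ds = 0.0
            elif spec.waveform == "sinusoid":
                w = 2.0 * np.pi * spec.frequency_hz / 1000.0
                ds = spec.amplitude * w * np.cos(w * t + spec.phase)
            else:
                h = 1e-6
                ds = (stimulus_current(spec, t + h, view)
                      - stimulus_current(spec, t - h, view)) / (2 * h)
            if intracellular:
                out[spec.target] += ds
            else:
                out += ds * patterns[k]
        return out


def assemble(network: Network, models: dict[str, MembraneModel],
             stimuli=(), synapses=(), medium: ExtracellularMedium | None = None,
             options: SolverOptions | None = None,
             sampling: SamplingSpec | None = None) -> CoupledSystem:
    """Build a :class:`CoupledSystem` (axial matrix, state layout, and — in
    closed loop — the transfer matrix and its elimination operators)."""
    return CoupledSystem(network, models, stimuli, synapses, medium,
                         options or SolverOptions(), sampling)


# ---------------------------------------------------------------------------
# current bookkeeping
# ---------------------------------------------------------------------------

def membrane_currents(system: CoupledSystem, t, x, vout=None) -> np.ndarray:
    """Total membrane current per segment (nA, outward), axial-side form:
    I_m,i = sum_j (Vin_j - Vin_i)/R_ij + I_gap,i + I_inj,i.  Identical (to
    solver tolerance) to C dVm/dt + I_ion area - I_syn from the membrane
    side.  These are the field sources of the closed loop."""
    vm = x[:system.n]
    if vout is None:
        vout = system.vout_of(t, x)
    return (system.axial @ (vm + vout) + system.gap @ vm
            + system.injected_currents(t, x))


def ephaptic_currents(system: CoupledSystem, vout: np.ndarray) -> np.ndarray:
    """i_eph,i = sum_j (Vout_j - Vout_i) / R_ij (nA)."""
    vout = np.asarray(vout, dtype=float)
    if vout.shape[0] != system.n:
        raise ValidationError("vout length must equal n_segments")
    return system.axial @ vout


# ---------------------------------------------------------------------------
# adaptive integration
# ---------------------------------------------------------------------------

def _event_breakpoints(system: CoupledSystem, t0: float, t1: float):
    """Pre-set external spike times inside (t0, t1], with synapse indices."""
    marks: list[tuple[float, int]] = []
    for k, spec in enumerate(system.syn_specs):
        if spec.kind == "external_spikes":
            for ts in spec.pre:
                if t0 < ts <= t1:
                    marks.append((float(ts), k))
    return sorted(marks)


def _chemical_events(system: CoupledSystem, last_fire: dict):
    """Terminal upward-crossing events on presynaptic Vm; each event is
    blanked (held at -1) during its own refractory window so integration
    restarts at a spike cannot re-trigger at the restart point."""
    evts = []
    for k, spec in enumerate(system.syn_specs):
        if spec.kind != "chemical":
            continue

        def make(k=k, spec=spec):
            def ev(t, x):
                if t < last_fire[k] + spec.refractory:
                    return -1.0
                return x[spec.pre] - spec.threshold
            ev.terminal = True
            ev.direction = 1.0
            return ev

        evts.append((k, make()))
    return evts


def _integrate_adaptive(system: CoupledSystem, t_span, mode, rhs, jac,
                        x0, n_aug):
    """Piecewise solve_ivp/BDF with synapse event handling; returns the
    dense-grid times and state matrix plus solver statistics.

    States are stored only at the output grid (`t_eval`); full dense output
    is retained per integration chunk only when chemical-synapse events
    require locating crossings, keeping memory flat on long runs.
    """
    opts = system.options
    t0, t1 = t_span
    grid = t0 + opts.dense_output_dt * np.arange(
        int(np.floor((t1 - t0) / opts.dense_output_dt + 1e-9)) + 1)
    X = np.empty((n_aug, len(grid)))
    stats = {"rhs_evals": 0, "jac_evals": 0, "lu_decompositions": 0,
             "events": 0}

    last_fire = {k: -np.inf for k, s in enumerate(system.syn_specs)
                 if s.kind == "chemical"}
    chem = _chemical_events(system, last_fire)
    use_dense = bool(chem)
    breakpoints = _event_breakpoints(system, t0, t1)
    bp_iter = iter(breakpoints + [(np.inf, -1)])
    next_bp, next_bp_syn = next(bp_iter)

    x = x0.copy()
    t = t0
    X[:, 0] = x
    filled = 1
    while t < t1 - 1e-12:
        t_stop = min(t1, next_bp)
        t_eval = grid[(grid > t + 1e-12) & (grid <= t_stop + 1e-12)]
        if len(t_eval) == 0 or abs(t_eval[-1] - t_stop) > 1e-12:
            t_eval = np.append(t_eval, t_stop)
        sol = solve_ivp(rhs, (t, t_stop), x, method="BDF",
                        rtol=opts.rel_tol, atol=opts.abs_tol,
                        max_step=opts.max_step, jac=jac,
                        events=[ev for _, ev in chem] or None,
                        t_eval=t_eval, dense_output=use_dense)
        if not sol.success:
            raise SolverError(
                f"integrator failed at t = {sol.t[-1]:.6g} ms: {sol.message}")
        stats["rhs_evals"] += sol.nfev
        stats["jac_evals"] += sol.njev
        stats["lu_decompositions"] += sol.nlu
        if sol.status == 1:  # terminated by a (chemical-synapse) event
            times = [te[-1] for te in sol.t_events if len(te)]
            t_end = float(max(times)) if times else float(sol.t[-1])
            x = sol.sol(t_end).copy()
        else:
            t_end = float(sol.t[-1])
            x = sol.y[:, -1].copy()
        for j, tj in enumerate(sol.t):
            if tj > t_end + 1e-12:
                break
            if filled < len(grid) and abs(tj - grid[filled]) < 1e-9:
                X[:, filled] = sol.y[:, j]
                filled += 1
        t = t_end
        fired = [k for (k, _), te in zip(chem, sol.t_events or []) if len(te)]
        for k in fired:
            spec = system.syn_specs[k]
            # confirm a genuine upward crossing (the refractory blanking can
            # produce a sign jump if Vm is still suprathreshold at release)
            before = sol.sol(max(t_end - 1e-3, sol.t[0]))[spec.pre]
            if (t - last_fire[k] >= spec.refractory
                    and before < spec.threshold <= x[spec.pre] + 1e-12):
                stats["events"] += 1
                base = system.syn_slice.start + 2 * k
                x[base] += 1.0
                x[base + 1] += 1.0
                last_fire[k] = t
        if abs(t - next_bp) < 1e-12:
            stats["events"] += 1
            base = system.syn_slice.start + 2 * next_bp_syn
            x[base] += 1.0
            x[base + 1] += 1.0
            next_bp, next_bp_syn = next(bp_iter)
    while filled < len(grid):  # numerical edge: grid point at exact t1
        X[:, filled] = x
        filled += 1
    return grid, X, stats


def _package_result(system: CoupledSystem, grid, X, mode, stats,
                    formulation) -> SimulationResult:
    n = system.n
    if X.shape[0] > system.n_states:   # DAE run carries Vout explicitly
        vout = X[system.n_states:, :]
        X = X[:system.n_states, :]
    else:
        vout = np.empty((n, len(grid)))
        for k, t in enumerate(grid):
            vout[:, k] = system.vout_of(t, X[:, k], mode)
    vm = X[:n, :]
    im = np.empty((n, len(grid)))
    for k, t in enumerate(grid):
        im[:, k] = membrane_currents(system, t, X[:, k], vout[:, k])
    gating = {}
    gating_segments = {}
    for g in system.groups:
        block = X[g.state_slice, :].reshape(g.model.n_states, len(g.seg_idx),
                                            len(grid))
        for s, name in enumerate(g.model.state_names):
            key = f"{g.tag}.{name}"
            gating[key] = block[s]
            gating_segments[key] = g.seg_idx.copy()
    meta = {
        "mode": mode,
        "formulation": formulation,
        "rel_tol": system.options.rel_tol,
        "abs_tol": system.options.abs_tol,
        "seed": system.options.seed,
        "sigma": None if system.medium is None else system.medium.sigma,
        "geometry_hash": geometry_hash(system.network),
        "solver_stats": stats,
        "cell_index": system.cell_index.copy(),
    }
    return SimulationResult(times=grid, vm=vm, vout=vout, gating=gating,
                            gating_segments=gating_segments,
                            membrane_currents=im, metadata=meta)


def solve_closed_loop(system: CoupledSystem, t_span,
                      x0: np.ndarray | None = None) -> SimulationResult:
    """Integrate with the extracellular potentials fed back (ephaptic on)."""
    if system.options.mode != "closed_loop":
        raise ValidationError("system was assembled for open loop")
    opts = system.options
    if x0 is None:
        x0 = system.initial_state()
    if opts.formulation == "mass_matrix_dae":
        vout0 = system.vout_of(t_span[0], x0, "closed_loop")
        z0 = np.concatenate([x0, vout0])
        grid, Z, stats = _integrate_adaptive(
            system, t_span, "closed_loop", system.dae_rhs, None, z0,
            system.n_states + system.n)
        return _package_result(system, grid, Z, "closed_loop", stats,
                               "mass_matrix_dae")
    grid, X, stats = _integrate_adaptive(
        system, t_span, "closed_loop",
        lambda t, x: system.rhs(t, x, "closed_loop"),
        None if system._has_custom_state else
        (lambda t, x: system.jac(t, x, "closed_loop")),
        x0, system.n_states)
    return _package_result(system, grid, X, "closed_loop", stats,
                           "eliminated_ode")


def solve_open_loop(system: CoupledSystem, t_span,
                    x0: np.ndarray | None = None) -> SimulationResult:
    """Integrate with i_eph = 0 (post-hoc LFP available from the recorded
    membrane currents via the field module)."""
    if x0 is None:
        x0 = system.initial_state()
    grid, X, stats = _integrate_adaptive(
        system, t_span, "open_loop",
        lambda t, x: system.rhs(t, x, "open_loop"),
        None if system._has_custom_state else
        (lambda t, x: system.jac(t, x, "open_loop")),
        x0, system.n_states)
    return _package_result(system, grid, X, "open_loop", stats,
                           "eliminated_ode")


def solve(system: CoupledSystem, t_span,
          x0: np.ndarray | None = None) -> SimulationResult:
    if system.options.mode == "closed_loop":
        return solve_closed_loop(system, t_span, x0)
    return solve_open_loop(system, t_span, x0)


# ---------------------------------------------------------------------------
# independent fixed-step implicit reference integrator
# ---------------------------------------------------------------------------

def reference_solve(system: CoupledSystem, t_span, dt_fixed: float,
                    x0: np.ndarray | None = None,
                    record_dt: float | None = None,
                    mode: str | None = None,
                    jac_refresh: int = 250) -> SimulationResult:
    """Backward-Euler integration with (simplified) Newton iterations at a
    fixed step ``dt_fixed`` (ms).

    Shares the spatial discretization and physics with the adaptive solver
    but none of its time stepping: each step solves
    ``y - x_k - dt f(t_{k+1}, y) = 0`` by Newton with a periodically
    refreshed LU of (I - dt J).  Bit-identical across repeated runs.
    """
    if dt_fixed <= 0:
        raise ValidationError("dt_fixed must be > 0")
    mode = mode or system.options.mode
    t0, t1 = t_span
    record_dt = record_dt or system.options.dense_output_dt
    if x0 is None:
        x0 = system.initial_state()
    rhs = lambda t, x: system.rhs(t, x, mode)  # noqa: E731

    def jac_dense(t, x):
        J = system.jac(t, x, mode)
        if J is None:
            J = _fd_jacobian(rhs, t, x)
        elif sp.issparse(J):
            J = J.toarray()
        return J

    n_steps = int(round((t1 - t0) / dt_fixed))
    record_every = max(1, int(round(record_dt / dt_fixed)))
    grid_idx = list(range(0, n_steps + 1, record_every))
    grid = t0 + dt_fixed * np.array(grid_idx, dtype=float)
    X = np.empty((system.n_states, len(grid)))
    X[:, 0] = x0
    x = x0.copy()
    lu = None
    eye = np.eye(system.n_states)
    newton_tol = 1e-10
    rec = 1
    for k in range(n_steps):
        t_new = t0 + (k + 1) * dt_fixed
        if lu is None or k % jac_refresh == 0:
            lu = lu_factor(eye - dt_fixed * jac_dense(t_new, x))
        y = x + dt_fixed * rhs(t_new, x)  # explicit predictor
        converged = False
        for it in range(20):
            resid = y - x - dt_fixed * rhs(t_new, y)
            dy = lu_solve(lu, resid)
            y -= dy
            if np.max(np.abs(dy)) < newton_tol * max(1.0, np.max(np.abs(y))):
                converged = True
                break
            if it == 9:  # refresh the Jacobian once before giving up
                lu = lu_factor(eye - dt_fixed * jac_dense(t_new, y))
        if not converged:
            raise SolverError(
                f"reference Newton failed to converge at step {k} "
                f"(t = {t_new:.6g} ms)")
        x = y
        if rec < len(grid) and k + 1 == grid_idx[rec]:
            X[:, rec] = x
            rec += 1
    stats = {"steps": n_steps, "dt_fixed": dt_fixed}
    res = _package_result(system, grid, X, mode, stats, "reference_be")
    res.metadata["integrator"] = "backward_euler_newton"
    return res


def _fd_jacobian(rhs, t, x, eps=1e-7):
    f0 = rhs(t, x)
    J = np.empty((len(x), len(x)))
    for i in range(len(x)):
        xp = x.copy()
        xp[i] += eps
        J[:, i] = (rhs(t, xp) - f0) / eps
    return J


# ---------------------------------------------------------------------------
# limit-cycle initialization
# ---------------------------------------------------------------------------

def randomized_limit_cycle_init(system: CoupledSystem, rng,
                                settle_ms: float | None = None,
                                threshold: float = 0.0) -> np.ndarray:
    """Start every cell at a uniformly random phase of its own limit cycle.

    Each cell is settled in isolation (open loop decouples cells that share
    no synapses) for ``settle_ms``, its period is measured from the late
    spike times of its first segment, and the returned initial state samples
    each cell's trajectory at an independent random phase of the final
    period.  Cells that do not spike keep their settled end state.
    """
    settle_ms = settle_ms or system.options.settle_time
    res = solve_open_loop(system, (0.0, settle_ms))
    # reconstruct the packed state trajectory from the result blocks
    X = np.empty((system.n_states, len(res.times)))
    X[:system.n, :] = res.vm
    for g in system.groups:
        for s, name in enumerate(g.model.state_names):
            rows = g.state_slice.start + s * len(g.seg_idx) \
                + np.arange(len(g.seg_idx))
            X[rows, :] = res.gating[f"{g.tag}.{name}"]
    X[system.syn_slice, :] = 0.0

    from .analysis import detect_spikes  # local import to avoid a cycle

    x0 = X[:, -1].copy()
    t = res.times
    for ci in range(len(system.network.cells)):
        seg_ids = np.where(system.cell_index == ci)[0]
        lead = seg_ids[0]
        train = detect_spikes(t, res.vm[lead], threshold=threshold)
        if len(train.times) < 3:
            continue
        period = train.times[-1] - train.times[-2]
        phase = rng.uniform(0.0, 1.0)
        t_sample = train.times[-1] - phase * period
        k = int(np.clip(np.searchsorted(t, t_sample), 1, len(t) - 1))
        # linear interpolation between stored samples
        w = (t_sample - t[k - 1]) / (t[k] - t[k - 1])
        sample = (1 - w) * X[:, k - 1] + w * X[:, k]
        x0[seg_ids] = sample[seg_ids]
        for g in system.groups:
            mask = np.isin(g.seg_idx, seg_ids)
            for s in range(g.model.n_states):
                rows = g.state_slice.start + s * len(g.seg_idx) \
                    + np.arange(len(g.seg_idx))
                x0[rows[mask]] = sample[rows[mask]]
    return x0


def geometry_hash(network: Network) -> str:
    h = hashlib.sha256()
    for s in network.segments:
        h.update(np.round(np.concatenate(
            [s.center, s.axis_start, s.axis_end,
             [s.radius, s.area]]), 9).tobytes())
    return h.hexdigest()[:16]
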