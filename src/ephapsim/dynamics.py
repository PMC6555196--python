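"""Membrane dynamics: continuous model contract, HH and passive models,
stimuli and synapses.

A :class:`MembraneModel` is any *continuous* dynamical system of the form

    i_ion = f(t, Vm, state, params)          [mA/cm^2]
    d(state)/dt = g(t, Vm, state, params)    [1/ms]

evaluated vectorized over segments.  Hybrid models that reset their state
discontinuously (integrate-and-fire, Izhikevich) are outside this contract:
the coupled extracellular solver requires a continuous right-hand side.

The shipped Hodgkin-Huxley model is the classic squid-axon formulation at
6.3 degC with the standard rate functions

    alpha_m = 0.1 (V+40) / (1 - exp(-(V+40)/10))
    beta_m  = 4 exp(-(V+65)/18)
    alpha_h = 0.07 exp(-(V+65)/20)
    beta_h  = 1 / (1 + exp(-(V+35)/10))
    alpha_n = 0.01 (V+55) / (1 - exp(-(V+55)/10))
    beta_n  = 0.125 exp(-(V+65)/80)

and defaults gNa = 120, gK = 36, gL = 0.3 mS/cm^2; ENa = 50, EK = -77,
EL = -54.3 mV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq

from .errors import StimulusError, ValidationError
from .units import NS_MV_TO_NA

__all__ = [
    "MembraneModel",
    "hh_model",
    "passive_model",
    "StimulusSpec",
    "stimulus_current",
    "SynapseSpec",
    "synaptic_current",
    "biexp_peak_time",
    "biexp_normalization",
]


# ---------------------------------------------------------------------------
# membrane model contract
# ---------------------------------------------------------------------------

@dataclass
class MembraneModel:
    """Continuous membrane dynamics bound per segment.

    Attributes
    ----------
    name : str
    state_names : tuple of str
        Ordered gating-variable identifiers (may be empty).
    params : dict
        Named constants (conductances in mS/cm^2, reversals in mV).
    evaluate : callable(t, Vm, state, params) -> (i_ion, dstate)
        ``Vm`` is an (n,) array (mV), ``state`` an (n_states, n) array;
        returns ionic current per area in mA/cm^2 (outward positive) and
        the gating derivatives per ms, both vectorized.
    initial_state : callable(Vm, params) -> state
        Steady-state gating values for a (possibly array) Vm.
    """

    name: str
    state_names: tuple[str, ...]
    params: dict[str, float]
    evaluate: Callable
    initial_state: Callable

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    def resting_potential(self, lo: float = -90.0, hi: float = -40.0) -> float:
        """Vm at which the steady-state ionic current vanishes."""

        def net(v):
            s = self.initial_state(np.array([v]), self.params)
            i, _ = self.evaluate(0.0, np.array([v]), s, self.params)
            return float(i[0])

        return brentq(net, lo, hi, xtol=1e-12)


def _vtrap(x: np.ndarray) -> np.ndarray:
    """x / (1 - exp(-x)), stable through x = 0."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = np.abs(x) < 1e-6
    out[small] = 1.0 + x[small] / 2.0
    xs = x[~small]
    out[~small] = xs / (1.0 - np.exp(-xs))
    return out


def hh_rates(v: np.ndarray):
    """Classic HH alpha/beta rate functions (1/ms) for m, h, n at Vm (mV)."""
    v = np.asarray(v, dtype=float)
    am = 1.0 * _vtrap((v + 40.0) / 10.0)
    bm = 4.0 * np.exp(-(v + 65.0) / 18.0)
    ah = 0.07 * np.exp(-(v + 65.0) / 20.0)
    bh = 1.0 / (1.0 + np.exp(-(v + 35.0) / 10.0))
    an = 0.1 * _vtrap((v + 55.0) / 10.0)
    bn = 0.125 * np.exp(-(v + 65.0) / 80.0)
    return am, bm, ah, bh, an, bn


_HH_DEFAULTS = dict(gna=120.0, gk=36.0, gl=0.3, ena=50.0, ek=-77.0, el=-54.3)


def hh_model(**overrides) -> MembraneModel:
    """The classic Hodgkin-Huxley Na/K/leak model (squid axon, 6.3 degC).

    Keyword overrides replace the default parameters ``gna``, ``gk``, ``gl``
    (mS/cm^2) and ``ena``, ``ek``, ``el`` (mV).
    """
    params = dict(_HH_DEFAULTS)
    unknown = set(overrides) - set(params)
    if unknown:
        raise ValidationError(f"unknown HH parameters {sorted(unknown)}")
    params.update(overrides)
    for g in ("gna", "gk", "gl"):
        if params[g] < 0:
            raise ValidationError(f"HH conductance {g} must be >= 0")

    def evaluate(t, vm, state, p):
        m, h, n = state
        am, bm, ah, bh, an, bn = hh_rates(vm)
        # mS/cm^2 * mV = uA/cm^2; convert to mA/cm^2
        i_ion = 1e-3 * (p["gna"] * m ** 3 * h * (vm - p["ena"])
                        + p["gk"] * n ** 4 * (vm - p["ek"])
                        + p["gl"] * (vm - p["el"]))
        dstate = np.stack([am * (1.0 - m) - bm * m,
                           ah * (1.0 - h) - bh * h,
                           an * (1.0 - n) - bn * n])
        return i_ion, dstate

    def initial_state(vm, p):
        vm = np.atleast_1d(np.asarray(vm, dtype=float))
        am, bm, ah, bh, an, bn = hh_rates(vm)
        return np.stack([am / (am + bm), ah / (ah + bh), an / (an + bn)])

    return MembraneModel(name="hh", state_names=("m", "h", "n"),
                         params=params, evaluate=evaluate,
                         initial_state=initial_state)


def passive_model(g_leak: float = 0.3, e_leak: float = -65.0) -> MembraneModel:
    """Leak-only membrane: i_ion = g_leak * (Vm - e_leak), no gating."""
    if g_leak < 0:
        raise ValidationError("g_leak must be >= 0")
    params = dict(gl=g_leak, el=e_leak)

    def evaluate(t, vm, state, p):
        i_ion = 1e-3 * p["gl"] * (vm - p["el"])
        return i_ion, np.zeros((0, vm.shape[0]))

    def initial_state(vm, p):
        vm = np.atleast_1d(np.asarray(vm, dtype=float))
        return np.zeros((0, vm.shape[0]))

    return MembraneModel(name="passive", state_names=(), params=params,
                         evaluate=evaluate, initial_state=initial_state)


#: registry used by config files; custom models can be registered here
MODEL_REGISTRY: dict[str, Callable[..., MembraneModel]] = {
    "hh": hh_model,
    "passive": passive_model,
}


# ---------------------------------------------------------------------------
# stimuli
# ---------------------------------------------------------------------------

@dataclass
class StimulusSpec:
    """An intracellular current injection or an extracellular source.

    The scalar waveform value s(t) (see :func:`stimulus_current`) is
    interpreted according to ``side``:

    * ``intracellular``: s(t) is a current (nA) injected into segment
      ``target`` (return electrode at infinity; the injected current is not
      itself an extracellular source).
    * ``extracellular`` with ``electrode='point'``: s(t) is a point-source
      current (nA) at ``position``.
    * ``extracellular`` with ``electrode='plates'``: s(t) is the magnitude
      (mV/um) of a uniform field along the unit vector ``field_direction``;
      the imposed potential is V(x) = -E . x.
    """

    target: int | None = None
    side: str = "intracellular"
    waveform: str = "dc"
    amplitude: float = 0.0
    frequency_hz: float = 0.0
    phase: float = 0.0
    custom_fn: Callable | None = None
    electrode: str = "point"
    position: Sequence[float] = (0.0, 0.0, 0.0)
    field_direction: Sequence[float] = (0.0, 0.0, 1.0)

    def __post_init__(self):
        if self.side not in ("intracellular", "extracellular"):
            raise ValidationError(f"unknown stimulus side {self.side!r}")
        if self.waveform not in ("dc", "sinusoid", "custom"):
            raise ValidationError(f"unknown waveform {self.waveform!r}")
        if self.waveform == "sinusoid" and self.frequency_hz < 0:
            raise ValidationError("sinusoid frequency must be >= 0")
        if self.waveform == "custom" and self.custom_fn is None:
            raise ValidationError("custom waveform requires custom_fn")
        if self.side == "intracellular" and self.target is None:
            raise ValidationError("intracellular stimulus requires a target")
        if self.electrode not in ("point", "plates"):
            raise ValidationError(f"unknown electrode kind {self.electrode!r}")


def stimulus_current(spec: StimulusSpec, t: float, state=None) -> float:
    """Scalar waveform value at time t (ms); units depend on ``spec.side``."""
    if spec.waveform == "dc":
        return spec.amplitude
    if spec.waveform == "sinusoid":
        return spec.amplitude * math.sin(
            2.0 * math.pi * spec.frequency_hz * t / 1000.0 + spec.phase)
    try:
        return float(spec.custom_fn(t, state))
    except Exception as exc:  # noqa: BLE001 - context required by contract
        raise StimulusError(
            f"custom stimulus raised at t = {t:.6g} ms: {exc!r}") from exc


# ---------------------------------------------------------------------------
# synapses
# ---------------------------------------------------------------------------

@dataclass
class SynapseSpec:
    """Chemical synapse, gap junction, or external pre-set spike input.

    Chemical and external synapses use a difference-of-exponentials
    conductance: each presynaptic spike adds a unit impulse to both decaying
    states, g(t) = g_max * norm * (s_decay - s_rise), normalized so a single
    isolated spike peaks at exactly ``g_max``.  Synaptic current (outward
    positive) is I = g(t) * (V_post - e_syn).  Gap junctions are ohmic on
    the membrane potentials: I_post = g_max * (V_post - V_pre).
    """

    kind: str = "chemical"
    pre: int | Sequence[float] | None = None
    post: int = 0
    g_max: float = 1.0           # nS
    e_syn: float = 0.0           # mV
    tau_rise: float = 0.5        # ms
    tau_decay: float = 3.0       # ms
    threshold: float = 0.0       # mV, presynaptic spike detection
    refractory: float = 2.0      # ms

    def __post_init__(self):
        if self.kind not in ("chemical", "gap", "external_spikes"):
            raise ValidationError(f"unknown synapse kind {self.kind!r}")
        if self.g_max < 0:
            raise ValidationError("g_max must be >= 0")
        if self.kind != "gap" and not self.tau_rise < self.tau_decay:
            raise ValidationError("tau_rise must be < tau_decay")
        if self.kind == "external_spikes":
            self.pre = tuple(float(t) for t in np.sort(np.asarray(self.pre)))

    @property
    def n_states(self) -> int:
        return 0 if self.kind == "gap" else 2


def biexp_peak_time(tau_rise: float, tau_decay: float) -> float:
    """Peak time (ms after a spike) of exp(-t/tau_d) - exp(-t/tau_r)."""
    return (tau_rise * tau_decay / (tau_decay - tau_rise)
            * math.log(tau_decay / tau_rise))


def biexp_normalization(tau_rise: float, tau_decay: float) -> float:
    """Scale factor making a single-spike conductance transient peak at 1."""
    tp = biexp_peak_time(tau_rise, tau_decay)
    return 1.0 / (math.exp(-tp / tau_decay) - math.exp(-tp / tau_rise))


def synaptic_current(spec: SynapseSpec, t: float, v_post: float,
                     v_pre: float | None = None,
                     syn_state: np.ndarray | None = None):
    """Instantaneous synaptic current (nA, outward positive at ``post``)
    and the time derivatives of the synapse state.

    For chemical/external synapses ``syn_state = (s_rise, s_decay)``; spike
    events increment both states by 1 *between* integrator steps (event
    handling lives in the solver), so this function is continuous.
    """
    if spec.kind == "gap":
        if v_pre is None:
            raise ValidationError("gap junction requires v_pre")
        return NS_MV_TO_NA * spec.g_max * (v_post - v_pre), np.zeros(0)
    s_rise, s_decay = syn_state
    norm = biexp_normalization(spec.tau_rise, spec.tau_decay)
    g = spec.g_max * norm * (s_decay - s_rise)  # nS
    i = NS_MV_TO_NA * g * (v_post - spec.e_syn)
    dstate = np.array([-s_rise / spec.tau_rise, -s_decay / spec.tau_decay])
    return i, dstate
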