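"""The axon-bundle phase-locking experiment.

Seven parallel axons (one central, six hexagonally tiled at ~5 um pitch),
all with classic HH dynamics, are set into an oscillatory firing regime by
per-axon DC injections into the first segment.  The injections are tuned so
the *isolated* firing rates spread by about +/-8% around a common mean with
period ~12.5 ms; each axon starts at a random point on its own limit cycle
(seeded).  Closed-loop runs across extracellular conductivities reveal
ephaptic phase locking: cross-correlation peaks at zero lag and near half
the period emerge as sigma drops toward 5e-4 S/m, and vanish in open loop.

The DC tuning procedure measures the isolated rate-vs-current curve of one
bundle axon at a few anchor currents and inverts it by monotone
interpolation; :data:`DEFAULT_DC_AMPLITUDES_NA` caches its output for the
default bundle geometry.
"""

from __future__ import annotations

import numpy as np

from .analysis import detect_spikes
from .dynamics import hh_model, StimulusSpec
from .errors import ValidationError
from .field import ExtracellularMedium
from .morphology import BUNDLE_NSEG, BUNDLE_PITCH, fixture_network
from .solver import (SolverOptions, assemble, randomized_limit_cycle_init,
                     solve)

__all__ = [
    "FREQUENCY_OFFSETS",
    "DEFAULT_DC_AMPLITUDES_NA",
    "isolated_rate",
    "tune_dc_amplitudes",
    "run_bundle",
]

#: fixed per-axon fractional detunings (axon 0 = central), spanning ~+/-8%
#: around the common mean rate, interleaved so ring neighbors differ.
FREQUENCY_OFFSETS = np.array(
    [0.0, 0.08, -0.053, 0.027, -0.08, 0.053, -0.027])

#: mean target period (ms) of the oscillatory regime
TARGET_PERIOD_MS = 12.5

#: cached output of ``tune_dc_amplitudes()`` for the default bundle
#: geometry (L = 1000 um, d = 2 um, nseg = 15), per axon, in nA.
DEFAULT_DC_AMPLITUDES_NA = np.array(
    [0.367, 0.449, 0.320, 0.391, 0.297, 0.418, 0.343])


def isolated_rate(amplitude_na: float, nseg: int = BUNDLE_NSEG,
                  t_sim: float = 600.0, **fixture_params) -> float:
    """Steady firing rate (Hz) of one isolated bundle axon under DC drive,
    measured from the late-half inter-spike intervals at mid-axon."""
    net = fixture_network("axon", nseg=nseg, **fixture_params)
    system = assemble(
        net, {"hh": hh_model()},
        [StimulusSpec(target=0, waveform="dc", amplitude=amplitude_na)],
        options=SolverOptions(mode="open_loop"))
    res = solve(system, (0.0, t_sim))
    tr = detect_spikes(res.times, res.vm[net.n_segments // 2])
    late = tr.times[tr.times > t_sim / 2]
    if len(late) < 3:
        return 0.0
    return 1000.0 / float(np.mean(np.diff(late)))


def tune_dc_amplitudes(target_period_ms: float = TARGET_PERIOD_MS,
                       offsets: np.ndarray = FREQUENCY_OFFSETS,
                       anchors_na=(0.2, 0.3, 0.4, 0.5, 0.7),
                       nseg: int = BUNDLE_NSEG, t_sim: float = 600.0,
                       **fixture_params) -> np.ndarray:
    """Per-axon DC amplitudes (nA) hitting rates f0*(1 + offsets).

    The rate-current curve is sampled at ``anchors_na`` (must bracket the
    targets and be monotone over them) and inverted by interpolation.
    """
    rates = np.array([isolated_rate(a, nseg=nseg, t_sim=t_sim,
                                    **fixture_params) for a in anchors_na])
    if np.any(np.diff(rates) <= 0):
        raise ValidationError(
            "rate-current anchors are not monotone; adjust anchors_na")
    f0 = 1000.0 / target_period_ms
    targets = f0 * (1.0 + np.asarray(offsets))
    if targets.min() < rates.min() or targets.max() > rates.max():
        raise ValidationError("target rates outside the anchored f(I) range")
    return np.interp(targets, rates, np.asarray(anchors_na))


def run_bundle(sigma: float, seed: int, t_sim: float = 2000.0,
               amplitudes_na: np.ndarray | None = None,
               ephaptic: bool = True, nseg: int = BUNDLE_NSEG,
               pitch: float = BUNDLE_PITCH, settle_ms: float = 400.0,
               rel_tol: float = 1e-6, abs_tol: float = 1e-8,
               **fixture_params):
    """One seeded bundle simulation at one conductivity.

    ``ephaptic=False`` runs the identical network open loop (the control
    condition).  The initial state places every axon at an independent
    uniformly random phase of its isolated limit cycle.
    """
    amps = (np.asarray(amplitudes_na) if amplitudes_na is not None
            else DEFAULT_DC_AMPLITUDES_NA)
    net = fixture_network("hex_bundle", nseg=nseg, pitch=pitch,
                          **fixture_params)
    if len(amps) != len(net.cells):
        raise ValidationError("need one DC amplitude per axon")
    stimuli = [StimulusSpec(target=i * nseg, waveform="dc",
                            amplitude=float(a)) for i, a in enumerate(amps)]
    opts = SolverOptions(mode="closed_loop" if ephaptic else "open_loop",
                         rel_tol=rel_tol, abs_tol=abs_tol, seed=seed,
                         settle_time=settle_ms)
    system = assemble(net, {"hh": hh_model()}, stimuli,
                      medium=ExtracellularMedium(sigma), options=opts)
    rng = np.random.default_rng(seed)
    x0 = randomized_limit_cycle_init(system, rng, settle_ms)
    return solve(system, (0.0, t_sim), x0)
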