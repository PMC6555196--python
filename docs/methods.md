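# Methods

## The model

`ephapsim` simulates networks of compartmental spiking neurons together
with the extracellular potentials their membrane currents generate, in two
regimes:

* **open loop** — the classical post-hoc LFP computation: the cable
  equation is integrated first, and extracellular potentials are evaluated
  afterwards from the recorded membrane currents;
* **closed loop** — the extracellular potential of every segment is part of
  the dynamical system and feeds back into the membrane equations as an
  *ephaptic current*, so membrane dynamics and fields are solved
  self-consistently at every step.

### Cable equation

Each cell is a tree of *sections* (spheres for somata, cylinders for
neurites), discretized into *segments* — the solution nodes.  For segment
i with membrane potential `Vm_i = Vin_i − Vout_i`:

    C_i dVm_i/dt + I_ion_i(Vm_i, s_i) · A_i
        = Σ_j (Vin_j − Vin_i) / R_ij + I_inj_i + I_gap_i + I_syn_i

with `C_i` the segment capacitance, `A_i` its membrane area, `s_i` the
gating state, and `R_ij` the axial resistance between neighboring segments
(standard half-segment series rule `R = Ra·ℓ/(π r²)`; spheres are
isopotential and couple through the attached cylinder's half-segment
resistance only).  Splitting `Vin = Vm + Vout` isolates the ephaptic drive

    i_eph_i = Σ_j (Vout_j − Vout_i) / R_ij .

### Extracellular potentials

The medium is homogeneous, isotropic and ohmic (conductivity σ, S/m), so
the potential solves a Poisson equation whose elementary solutions are used
in closed form (no finite elements): cylinders are line sources,

    V = I / (4πσL) · ln| (√(h²+r²) − h) / (√(l²+r²) − l) | ,

with `l` the signed axial distance from the cylinder beginning and
`h = l − L` from its end; spheres are point sources `V = I/(4πσR)`, clamped
to the surface value for `R < r_sphere`.  Superposition is exact.  The
per-segment `Vout` entering the dynamics is the kernel averaged over the
receiving segment's boundary (a 5 axial × 8 azimuthal grid on cylinder
lateral surfaces; an 8-point great-circle ring on spheres, its plane
anchored to the neighboring segment so coefficients are isometry
invariant).  End caps are not sampled.  The resulting dense matrix **T**
of mV-per-nA coefficients scales exactly as 1/σ.  The line-source prefactor
and sign convention were fixed by requiring exact agreement with an
independent quadrature oracle (dense sums of point sources along the axis);
that requirement determines the form uniquely.

Self-coefficients depend mildly on the sampling density (≈1% between the
default 5×8 layout and a 100×100 layout for a 10 µm × 1 µm segment); the
validation bounds are robust to this choice because both field paths in any
comparison use the same convention.

### Closed-loop solution

Field sources are the total per-segment transmembrane currents
(capacitive + ionic − synaptic, equivalently the axial-side bookkeeping
`I_m = A(Vm + Vout) + G_gap·Vm + I_inj`); the intracellular electrode
current itself does not cross the membrane and contributes no extra source
(its return electrode is at infinity).  The algebraic constraint

    Vout = T·I_m + V_stim(t)

is *linear* in `Vout`, so the default `eliminated_ode` formulation solves

    (Id − T·A)·Vout = T·((A + G_gap)·Vm + I_inj) + V_stim

exactly (one pre-factorized LU solve) inside every derivative evaluation,
yielding a stiff ODE in (Vm, gating, synapse) states that is mathematically
identical to the singular-mass-matrix DAE `M ẋ = f(x, t)`.  Stored
closed-loop results satisfy `Vout = T·I_m` to machine precision at every
output time.

The alternative `mass_matrix_dae` formulation keeps `Vout` as an explicit
algebraic block of the state vector.  SciPy has no stiff solver with a
singular mass matrix, so the constraint — being linear — is differentiated
once (index reduction) and `Vout` is integrated alongside the membrane
states from a consistent initialization.  It is a genuinely separate code
path used as a cross-check; the two formulations agree to integrator
tolerance (drift of the differentiated constraint is negligible on the
spans tested).

Integration uses SciPy's BDF with an analytic/semi-analytic Jacobian: the
axial, gap, ephaptic-elimination and synaptic parts are exact, and the
per-segment ionic block is obtained by vectorized finite differences on the
membrane model (one perturbed evaluation per state variable covers the
whole network because ionic currents are local).  Open-loop Jacobians are
sparse; closed-loop Jacobians are dense (ephaptic coupling is all-to-all —
the intrinsic O(n²) cost of the method).

### Membrane models, stimuli, synapses

Membrane models are *continuous* dynamical systems (ionic current per area
plus gating derivatives); hybrid reset models (integrate-and-fire,
Izhikevich) are out of contract.  Shipped models: the classic squid-axon
Hodgkin–Huxley model at 6.3 °C (gNa = 120, gK = 36, gL = 0.3 mS/cm²;
ENa = 50, EK = −77, EL = −54.3 mV; the standard α/β rate functions, written
with singularity-safe evaluation) and a passive leak.  Stimuli are DC,
sinusoidal or arbitrary user functions (time- and state-dependent),
intracellular (nA into a segment) or extracellular (point electrode, or
uniform parallel-plate field with potential −E·x; both superpose into
`Vout`).  Chemical and pre-set-spike-time synapses use a
difference-of-exponentials conductance normalized to peak at `g_max`;
presynaptic spikes are located with integrator event detection and the
conductance states are incremented *between* integration segments, keeping
the right-hand side continuous as the solver requires.  Gap junctions are
ohmic in the membrane potentials and enter the field sources through the
axial-side bookkeeping.

### Reference integrator

`reference_solve` is a fixed-step backward-Euler integrator with
(simplified) Newton iterations and periodic Jacobian refresh.  It shares
the spatial discretization and the physics evaluation with the adaptive
path but none of the time-stepping machinery, is bit-reproducible, and
first-order convergent.  It plays the role an external simulator plays in
cross-validation: at dt = 1 µs it provides an independent trajectory
against which the adaptive solver's Vm (RMS < 0.5 mV) and spike-peak
timing (< 20 µs, parabolic interpolation of peaks) are checked, and a
quadrature field evaluator (≥10⁴ point sources per segment) provides the
independent LFP path (pooled RMS < 1.7 µV and < 1.1% of signal RMS).

## The axon-bundle experiment

Seven parallel axons (L = 1000 µm, d = 2 µm), one central and six at the
vertices of a regular hexagon of circumradius 5 µm, all with HH dynamics.
Each axon receives DC in its first segment, tuned so the *isolated* firing
rates spread about ±8% around a mean period of 12.5 ms (the detunings are a
fixed interleaved pattern; the tuner measures one axon's rate–current curve
at a few anchors and inverts it by monotone interpolation —
`bundle.DEFAULT_DC_AMPLITUDES_NA` caches its output).  Initial conditions
place every axon at an independent, seeded, uniformly random phase of its
own limit cycle (cells are settled in isolation, the period is measured
from late spikes, and the state is sampled at a random phase of the final
period).

Closed-loop runs across σ are analyzed by binning spikes (1 ms) in a late
analysis window, cross-correlating all 21 unordered pairs over ±1 mean
period (Pearson correlation of overlapping bins — bounded and comparable
across pairs; the estimator choice matters only for peak *values*, not peak
*lags*), and aggregating peak value and lag across pairs and seeds.  The
mean correlation curve averages each pair's correlation in *both*
orientations: the orientation of an unordered pair is arbitrary, so the
lag sign carries no information and the aggregate must not depend on cell
indexing (the anti-phase peak of a 12.5 ms oscillator sits at 6.25 ms,
between the 6- and 7-ms bins of a one-sided curve; the
orientation-symmetric mean resolves it at the 6-ms bin).  At
σ = 5×10⁻⁴ S/m the mean correlation develops local maxima at lag 0
(synchronous locking) and at the 6 ms bin (anti-synchronous locking at half
the period); in open loop the mean correlation stays flat.  Locking
strength decreases toward larger σ.

### Problem sizes

Bundle axons use 15 segments each (105 segments, 420 state variables);
dense closed-loop algebra makes this the practical desk scale, and the
locking phenomenology is insensitive to the discretization.  The
acceptance recomputation simulates 1 s per seeded run and analyzes the
last 500 ms with three seeds; the test suite uses slightly smaller bundles
(11 segments per axon, 800 ms) for the same checks.  Validation fixtures
(single axon, ball-and-stick, bipolar, branched) use 41–83 segments and
30 ms of simulated time.

## Parameters and defaults

| parameter | default | units | notes |
|---|---|---|---|
| Cm | 1.0 | µF/cm² | specific membrane capacitance |
| Ra | 100 | Ω·cm | axial resistivity |
| σ | 0.3 | S/m | typical CNS extracellular conductivity |
| rel_tol / abs_tol | 1e-6 / 1e-8 | — / mV | tight enough for ~10 µs spike timing |
| dense_output_dt | 0.025 | ms | output grid |
| sampling | 5 × 8 | — | boundary-average layout |
| synapse τ_rise / τ_decay | 0.5 / 3.0 | ms | difference-of-exponentials |
| spike threshold / refractory | 0 / 2 | mV / ms | detection defaults |

## What the fixtures do and do not emulate

The fixture geometries are idealized (straight cylinders, isopotential
spherical somata, exactly parallel bundles); real axons are tortuous,
myelinated or varicose, and real extracellular media are inhomogeneous and
anisotropic — none of which is modeled (scalar uniform σ only).  Passing
validations therefore demonstrate numerical correctness of the solver and
field computation and the qualitative physics of ephaptic interaction at
low σ, not quantitative predictions for any specific tissue.  SWC import
supports realistic morphologies as a capability; multi-point SWC somata
are collapsed to one sphere of equal total surface area.

## Numerical choices and degenerate inputs

* Line-source kernel evaluated in a cancellation-free form; points on the
  singular axis segment raise an error, while on-axis points beyond the
  ends use the exact r→0 limit.
* (Id − T·A) is LU-factorized once per assembly; numerically singular
  systems (pathological σ/geometry combinations) raise a conditioning
  error naming σ and the geometry scale.
* Backward-Euler Newton uses an explicit predictor, tolerance 1e-10
  relative to state magnitude, and refreshes its Jacobian every 250 steps
  or on slow convergence.
* Cells with fewer than three settle-phase spikes keep their settled end
  state in the randomized limit-cycle initialization.
* Silent cells are excluded from pairwise locking analysis and counted in
  the returned table's metadata.
* Zero-variance spike-count vectors make the Pearson estimator undefined;
  this is reported as an error, never silently zeroed.

## Known limitations

* Anisotropic, inhomogeneous or frequency-dependent media are out of
  scope, as are method-of-images boundaries.
* Only continuous membrane models are solvable; discontinuous hybrid
  models are rejected by design.
* The closed loop is O(n²) in memory and time; thousands of segments are
  beyond the intended desk scale.
* The mass-matrix route integrates the index-reduced constraint; extremely
  long closed-loop spans could accumulate constraint drift (the default
  elimination has none).
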