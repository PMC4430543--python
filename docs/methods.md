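# Methods

## Model

`frachh` simulates conductance-based neurons whose membrane potential
obeys a *fractional-order* differential equation. The physical picture is
a non-ideal membrane capacitor (a constant-phase element): its
current–voltage law is I = Cm^a d^a v/dt^a with order 0 < a <= 1, which
makes the voltage dynamics depend on the entire voltage history
("capacitive memory"). With a = 1 every model in the package reduces
exactly to its classical counterpart.

Three spatial scales share one membrane model:

- **patch** — the space-clamped squid-axon membrane:
  Cm^a d^a v/dt^a = I(t) − g_Na m³h (v−E_Na) − g_K n⁴ (v−E_K) − g_L (v−E_L),
  with the standard 1952 gating rates in the rest-relative voltage
  convention (depolarization positive, E_Na = 115, E_K = −12, E_L = 10.6 mV,
  g_Na = 120, g_K = 36, g_L = 0.3 mS/cm²). Only v is fractional; the gates
  stay first order, because the memory being modeled is dielectric, not a
  property of channel gating.
- **cable** — a 1-cm axon discretized by the method of lines
  (dx = 0.5 mm, sealed ends), each node a patch plus an axial coupling
  term g (v_{i+1} − 2 v_i + v_{i−1})/dx².
- **network** — N = 50 patches coupled by instantaneous sigmoidal
  synapses, with Gaussian in-degrees (mean 25, sd 2.5), uniform
  presynaptic partners and a 10% excitatory fraction.

The **analytic** module carries the passive theory used to validate the
solver: Mittag-Leffler step responses and strength-duration curves,
constant-phase-element impedance, and the passive-cable Green's function.

## Numerical scheme

The fractional derivative is discretized in the Grunwald-Letnikov (GL)
form. With memory weights c_1 = a, c_k = (1 − (1+a)/k) c_{k−1}, the
explicit update is

    v_{n+1} = sum_{k=1}^{n+1} c_k v_{n+1−k} + (dt)^a f(t_n, v_n),

which is forward Euler for a = 1 (all weights beyond c_1 vanish). The
state starts at rest (v(0) = 0), under which the Riemann-Liouville,
Caputo and GL definitions coincide; non-zero fractional initial
conditions are rejected rather than approximated.

**Fast exact history evaluation.** The full-memory sum is O(n²) if done
naively. We evaluate it *exactly* with a two-part scheme: lags 1..B are
summed directly each step (B = 1024 for single compartments, 128 for
cables/networks), while lags in (B·2^(l−1), B·2^l] are handled at level l
by FFT-convolving each completed, aligned panel of B·2^(l−1) history
values with the matching weight slice into a far-field accumulator. Each
lag is covered exactly once, so the result equals the naive sum to
round-off (verified to ~1e-13 in the tests); the cost is O(n log² n).
The per-level weight-slice FFT is computed once and reused. A
short-memory (truncated) policy is available behind
`SolverConfig.memory_policy` for very long runs, with the error bounded
by the dropped tail weight; the default — and everything reported here —
uses full memory.

**Time steps.** Smaller orders need smaller explicit steps. Defaults
(validated by the convergence tests): dt = 1e-3 ms for a >= 0.8, 5e-4 for
0.5 <= a < 0.8, 1e-4 for a < 0.5. The integrator aborts with a
diagnostic when |v| exceeds 1000 mV or turns non-finite. Gate variables
are clamped to [0, 1] after each Euler update: the exact gate ODE never
leaves the unit interval, so clamping only removes Euler overshoot, which
occurs under extreme hyperpolarizing stimuli where the closing rates are
stiff; in the physiological regime it is a no-op.

## Mittag-Leffler evaluation

E_{a,b}(z) on the real line is computed by band dispatch:

- |z| <= 9^a: the power series. The alternating-sum cancellation grows
  like exp(|z|^(1/a)); the bound keeps it below ~1e-12 absolute.
- z < 0, |z| < 40: a spectral integral representation (the integrand
  decays like exp(−chi^(1/a))), integrated by composite Gauss-Legendre
  with panels refined around the spectral resonance that appears for
  a > 1/2. Verified to ~1e-12 against arbitrary-precision series and an
  independent Talbot Laplace inversion.
- z <= −40: the algebraic asymptotic series at its optimal truncation.
  Its onset is far slower at small orders than the classical
  exp(−|z|^{1/a}) estimate suggests, which is why the integral covers the
  whole mid band.

The passive cable is solved in the wavenumber domain, where the Green's
function is exactly G^(q, t) = t^(a−1) E_{a,a}(−(1+q²) t^a) in
normalized units (x in space constants, t in time constants); the
inverse cosine transform is done by trapezoidal quadrature on an
adaptively sized q-grid. The step response uses
(1 − E_{a,1}(−(1+q²)t^a))/(1+q²), written as the steady state e^{−|x|}/2
minus a rapidly decaying integral so no slowly convergent tail appears.

**Pseudo-velocity.** The sub-threshold "front" position is where the
response reaches one half of its *local* steady state; the
pseudo-velocity is the least-squares slope of position versus first
crossing time over x in [0.5, 2] space constants (the window avoids the
origin singularity and the far-field noise floor). For a = 1 this gives
1.98 lambda/tau, the classical value. For a < 1 the crossing curve is
strongly concave, so the fitted slope depends on the window: near-origin
/ early-time windows give front speeds that *increase* with decreasing
order, while windows beyond one space constant give the opposite sign of
trend. We keep the stated window and treat only the a = 1 value as
quantitative.

## Unit convention for the axial conductance

The axial conductance is quoted in uS. The discrete coupling is
(g/dx²)·(second difference) with g converted to mS, i.e. g = 7.06 uS
gives 2.824 mS/cm², commensurate with the membrane conductances. Under
this convention the classical (a = 1) spike propagates at 0.17 cm/ms
(1.7 m/s) for g = 7.06 uS and the measured fractional velocity gains
(a: 1 -> 0.4) are ~88% and ~65% for g = 7.06 and 0.706 uS — matching the
published values so closely that we regard the convention as settled.
The two gains differ only through the fixed 0.5-mm discretization (in
the continuum the cable equation is scale-invariant in sqrt(g)), so the
dx = 0.5 mm grid is part of the model definition, not a numerical
nuisance parameter.

## Scaled-conductance controls

The control experiments ask whether the fractional effects are explained
by the altered peak ionic currents alone: an a = 1 model is rerun with
g_Na, g_K, g_L rescaled so that peak |I_Na|, |I_K| and the maximum
depolarizing I_L match the fractional run (per node, for the cable).
Because peak currents are proportional to their conductances at a fixed
voltage waveform, the multipliers are the ratios target/baseline-peak —
a single proportional rescaling. We deliberately do *not* iterate this
match to convergence: the first-order model *saturates* its peak sodium
current a few percent below small-order targets (a faster upstroke
self-limits I_Na), so the exact-match problem has no root, and iterating
drifts along a degenerate g_Na-up/g_K-down direction that inflates the
conduction velocity without improving the match (we observed +350%
velocity at unchanged residual). The proportional control achieves the
peak pattern to within a few percent and reproduces the published
control behavior: spike-amplitude changes are captured, while the
conduction-velocity gain collapses to ~2% (vs ~88% in the fractional
cable) and firing *accelerates* instead of slowing. The achieved peak
mismatch is reported on the returned trajectory.

## Synaptic stand-ins and network conditions

The synapse constants are stand-ins (the published table is not
reproduced here): E_syn,ex = 70, E_syn,in = −12, V_syn = 20, k_syn = 2 mV.
g_syn was calibrated in two documented steps: the 3-coincident-input
rule (a 1.5-ms input of 3·g_syn·70 uA/cm² should reach the brief-pulse
threshold) gives 0.024 mS/cm², which however cannot sustain recurrent
activity after the stimulus; g_syn = 0.2 mS/cm² is the value at which
the a = 1 baseline reproduces the defining qualitative condition that
integer-order networks sustain activity for the whole simulation across
seeds. All network conclusions are therefore *trends across >= 12 seeded
architectures* (termination earlier at small order, excitatory charge
dropping faster than inhibitory), never absolute values.

The evoking protocol is fixed: a 40 uA/cm², 50-ms current in 13
randomly selected neurons of an N = 50 network. Activity duration is the
last spike time; "sustained" means a spike within the final 50 ms.
The published network simulations run 550 ms; the packaged trend test
uses a 100-ms horizon for both orders (the small-order networks
self-terminate right after the stimulus, near 50 ms, so the trend is
already decided well inside that horizon) and dt = 1.5e-4 ms for
a = 0.4, which reproduces the dt = 1e-4 patch spike times to three
decimals. With full memory, a 50-neuron, 100-ms, a = 0.4 network run
costs about half a minute on one core.

## Spike measurements

A spike is a local maximum of v above 40 mV (relative to rest) separated
by at least 2 ms, with parabolic peak interpolation; both constants are
exposed. This operational definition matters near excitation block,
where asymptotic spike peaks shrink through the 40-mV line (e.g. the
classical patch at I_app = 100 uA/cm² settles at ~45-mV peaks), so
firing-range upper limits I_2 inherit it; the trends in order are
unaffected. Thresholds are located by bisection to 0.5 uA/cm²;
refractoriness bisects the two-pulse interval to 0.05 ms; firing
frequency is reported both count-based over the final 30 ms of a 100-ms
run and as mean 1000/ISI (the instantaneous-frequency rise quoted in the
results is last-ISI minus first-ISI). Cable velocity is 0.5 cm divided
by the spike-peak time difference between x = 0.25 and 0.75 cm.
Constant-current injection at a single end node is diluted by the axial
load, so sustaining repetitive propagation needs ~40 uA/cm² where the
patch fires at 20.

## Known limitations

- The explicit scheme's stability boundary tightens quickly as the order
  drops; orders below ~0.35 need steps well under 1e-4 ms and are
  outside the tested envelope.
- Mittag-Leffler accuracy degrades to ~1e-6 relative within ~0.01 of
  a = 1 in the mid band (the spectral resonance narrows like sin(pi a)).
- The synthetic network architecture is a random digraph with possible
  self-loops and duplicate synapses, as produced by plain uniform
  sampling; no claim is made about physiological connectivity, and
  network results are seed-ensemble trends only.
- Sub-threshold pseudo-velocity for a < 1 is reported with its fit
  window because no window-free front speed exists for the heavy-tailed
  response.
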