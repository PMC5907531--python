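# Methods

## The gating models

The rapid delayed-rectifier potassium current I_Kr of the human heart
is carried by Kv11.1 (hERG1) channels assembled from two alternatively
processed isoforms.  hERG1a is the full-length subunit; hERG1b lacks
the N-terminal PAS domain and gates faster in every respect that
matters for repolarization: activation, deactivation, and recovery
from inactivation.  `hergkin` models each homotetramer as a
continuous-time Markov chain over five gating states

    C3 <-> C2 <-> C1 <-> O <-> I

with state probabilities governed by the master equation dp/dt = Q p.
Two topologies are shipped:

* **mmodel1** — the linear chain above.  Inactivation is reached only
  through the open state.
* **mmodel2** — adds a direct C1 <-> I edge, closing the {C1, O, I}
  loop.  The forward C1 -> I rate is part of the parameter set; the
  reverse I -> C1 rate is never free data but is derived from
  microscopic reversibility (see below).

Each directed transition i carries an exponential rate law

    k_i(V) = a_i * alpha_i * exp(b_i * beta_i * V)

with alpha_i in ms^-1, beta_i in mV^-1 and dimensionless correction
factors a_i, b_i (identity 1 unless a fit says otherwise).  The
(alpha, beta) pair can alternatively be generated from transition-state
thermodynamics, alpha = (kB T / h) exp(dS/R - dH/(R T)) and
beta = z F / (R T); this form is supported but no shipped parameter
set uses it.  The two intermediate transitions (`ain`, `bin`) are
voltage-independent (beta = 0).  Four parameter sets are shipped,
{mmodel1, mmodel2} x {hERG1a, hERG1b}, valid at room temperature
(296.15 K); physiological-temperature rate corrections are accepted
through the same correction-factor mechanism but no default values are
shipped.

Physical constants: R = 8.315 J/mol/K, kB = 1.381e-23 J/K,
h = 6.626e-34 J s, F = 96485 C/mol.

### Microscopic reversibility

For exponential rate laws, detailed balance around a loop at *every*
voltage splits into two independent constraints: the product of the
prefactors and the sum of the voltage coefficients must balance
clockwise against counterclockwise.  `constrain_reversibility`
therefore solves for both the alpha and the beta of the one constrained
edge per loop (I -> C1 in mmodel2) from the effective
(correction-applied) values of the other five edges.  Closure is exact
to rounding; `loop_closure_ratio` verifies it to 1e-10 at any voltage.

### Current

I_Kr = gKr * pO * (V - EK), with

    gKr = gKr0 * (T/35 - 55/7) * sqrt(Ko / 5.4 mM),   gKr0 = 0.024 pA/pF/mV.

The linear temperature factor equals 1 exactly at 310 K.  EK defaults
to the Nernst potential from the recording solutions (120 mM internal
potassium — 10 KCl + 110 K-aspartate pipette; 5.4 mM bath), about
−79.1 mV at 23 °C, and can be overridden.  In the cell and tissue
context the conductance scale is 0.0422 pA/pF/mV instead, the value
that matches the peak I_Kr of a full human ventricular ionic model at
1 Hz pacing.

## Propagation

All voltage-clamp protocols are step protocols, so within a segment Q
is constant and p(t) = exp(Q t) p0 exactly.  `propagate_segment`
diagonalizes the 5x5 generator and evaluates all sample times at once,
falling back to repeated multiplication by expm(Q dt) if the eigenbasis
condition number exceeds 1e10.  This removes ODE-solver tolerance from
the protocol layer entirely; the only knobs left are the measurement
sampling interval (0.1 ms default — it affects only where measurements
are read, not accuracy) and floating-point rounding.  The propagator
matches `scipy.linalg.expm` to ~1e-14 per state.  Probability is
renormalized per segment only when the drift is below 1e-9; larger
drift raises an error instead of being hidden.

A caution for anyone validating against explicit Euler: at −120 mV the
fastest shipped rate is ~190 ms^-1, and a dt = 1e-4 ms Euler reference
carries a first-order truncation error of ~3.6e-6 per state over the
5-ms interpulse of the deactivation protocol — larger than the exact
propagator's rounding error by nine orders of magnitude.  The
truncation signature (error halving with dt) is asserted in the test
suite.

Each sweep starts from the steady state at the holding potential
(−80 mV), computed from the null space of Q.

## Protocols and derived measurements

* **Steady-state activation (SSA)**: hold −80 mV; 1-s steps from −100
  to +40 mV (10-mV increment by default — the increment is a package
  choice, only the range is prescribed by the source data); 1-s tail
  at −100 mV.  Signed peak tail currents, normalized to the largest
  magnitude, are fit with a single Boltzmann 1/(1 + exp((V1/2 − V)/k)).
* **Envelope of tails**: +40 mV activation of 5–500 ms duration
  (default grid 5, 10, 20, 50, 100, 200, 300, 400, 500 ms), 3-s tail at
  −100 mV; normalized peak tails vs duration trace activation onset.
* **Deactivation**: 1-s activation at +40 mV, 5-ms repolarization to
  −120 mV (recovering channels from inactivation), then a 5-s test step
  at −120, −100, −60 or −40 mV.  The decaying tail is fit with a double
  exponential.  The 1-s activation and 5-s test durations are package
  defaults; the protocol's shape and the voltage list are prescribed.
* **Recovery from inactivation**: 1-s conditioning at +40 mV, then a
  test step (default 200 ms) at −100 / −50 mV; the rising (hooked)
  phase up to the current peak is fit with A(1 − exp(−t/tau)).  The
  conditioning design is a package choice: no standard protocol was
  prescribed, so the recovery taus are used for isoform orderings and
  ratios, not absolute comparisons.

Tail polarity is inferred from sign(V − EK); tails at −100/−120 mV are
inward.  A sample at a voltage-step boundary belongs to the preceding
segment.

### Exponential fitting and its limits

`exp_fit` seeds time constants from a log-linear probe of the decay,
constrains taus positive (optionally above a floor `tau_min`) and
reports components fastest-first.  Two-exponential fits of
near-degenerate decays are seed-sensitive, so the fitter tries several
tau splittings deterministically and keeps the best solution whose
components are distinct (ratio ≥ 1.5) and both carry ≥ 1% of the
amplitude.

Two transients contaminate deactivation tails and are excluded by
construction: the rising hook (window starts at the current peak) and
the O <-> I re-equilibration, whose time constant
1/(k_OI + k_IO) is known when the generating model is known — pass a
few multiples of `inactivation_exchange_time` as `skip_ms` and
`tau_min`.  Even so, a finite-window fit cannot measure a component
whose amplitude is below ~1% of the signal; for model-to-model
comparisons `deactivation_mode_taus` returns the exact slowest
relaxation eigenmodes of Q(V) instead, which is the assumption-free
definition of the model's deactivation components.

## Global fitting

The fit optimizes correction factors, not raw rates: alphas and betas
stay frozen at their reference values and the optimizer moves
(a_i, b_i) on a chosen subset of transitions — corr_a in log space
(bounds 0.01–100), corr_b linear (bounds 0.2–5).  The cost is a
weighted sum over datasets of squared residuals between simulated and
target *derived observables* (normalized SSA points, envelope curves,
peak-normalized deactivation time courses subsampled at 10 ms,
recovery taus) — the curves the protocols are designed to measure —
rather than raw traces.  Weights default to equal.  A simulation
failure at a proposed parameter point contributes a large finite
penalty rather than aborting the fit.

`global_fit` runs SciPy's bounded trust-region-reflective least
squares from n_starts points: the identity correction plus seeded
log-uniform draws within bounds.  The same seed reproduces the same
starts and hence the same result bit for bit.  `stability_check`
probes the cost with ±epsilon relative perturbations per parameter and
flags directions whose cost change is below a floor as unidentifiable.

Because no raw recordings are deposited for the shipped tables, the
fitting machinery is validated by synthetic recovery
(`generate_synthetic_dataset`): observables simulated from a known
truth, Gaussian noise with SD a configurable fraction of each
dataset's peak (2% for the headline check), recovery of known
corrections within 10% from 10 starts.  The generator emulates the
derived observables and their noise only — not capacitance transients,
series-resistance error, leak, or cell-to-cell variability — so a
passing recovery says the estimator is correct and identifiable at
these conditions, not that real-data fits reach that accuracy.

## Cell and tissue level

### Surrogate ventricular cell

The seam to cell models is narrow (`IonicModelInterface`): given
(V, state, dt, stimulus) return dV/dt, the updated state and named
currents.  A full reconstruction of a human ventricular ionic model is
deliberately out of scope; the shipped
`SurrogateVentricularModel` is a minimal excitable cell — described as
exactly that — built so that I_Kr controls late repolarization:

| current | form | default g (mS/uF) | role |
|---|---|---|---|
| I_fast | g m_inf(V) h (V − 50), tau_h = 1 ms | 6.0 | upstroke, propagation |
| I_plateau | g d_inf(V) f (V − 55), tau_f = 200 ms | 0.045 | dome/plateau |
| I_K1 | g r_inf(V) (V − EK) | 0.75 | resting potential |
| I_Kp | g x_inf(V) (V − EK) | 0.004 | plateau repolarization reserve |
| I_Kr | 0.0422 pO_mix (V − EK) | — | the Markov mixture current |

All gates are sigmoid; activation gates (m, d) are instantaneous,
inactivation gates (h, f) relax exponentially (exact exponential
update).  The defaults give a resting potential near −83 mV, a peak
near +40 mV, conduction at ~0.07 cm/ms on the default cable, and
APD90 ≈ 500 ms (pure hERG1a) to ≈ 290 ms (pure hERG1b) at 1-Hz pacing.
The fast-current conductance is set high enough that a propagating
wavefront has an adequate safety factor on a 165-cell strand; weaker
settings conduct decrementally and die mid-fiber.

An isoform mixture keeps one Markov state vector per isoform (both see
the same voltage, gate independently) and the mixture current is the
fraction-weighted sum — maximal single-channel conductance is assumed
identical for the two isoforms, so all differences are kinetic.  Cells
are initialized at the true resting equilibrium (root of the total
current with gates and Markov chains at steady state), so an
unstimulated cell stays at rest to float precision.

### Numerics of pacing

Voltage advances by forward Euler.  The step is 0.005 ms except while
the stimulus is on or while the previous step's max |dV/dt| exceeds an
upstroke threshold (default 30 mV/ms), when it drops to 0.00005 ms.
Within each step the Markov chains advance at frozen voltage (operator
splitting) by a classical RK4 step, which matches the matrix
exponential to ~1e-12 per state at dt = 0.005 ms; probability drift is
audited every beat against a 1e-6 tolerance and rounding-level drift
renormalized.  Inside the compiled kernel, transition rates and gate
sigmoids are linearly interpolated from a 0.02-mV table
(relative error ~2e-7, far below the Euler discretization error);
the API-level `MarkovIKrComponent.step` uses exact rates.

### Fiber and pseudo-ECG

The transmural strand is 165 cells at dx = 100 um, D = 0.00092 cm^2/ms,
Cm = 1 uF/cm^2, sealed ends, stimulus 300 uA/cm^2 for 0.5 ms to cell 1,
BCL 1000 ms.  Cell indices carry endo (1–60) / M (61–105) / epi
(106–165) labels; with the homogeneous surrogate they are bookkeeping
only, and become meaningful when a heterogeneous ionic model is plugged
in.  Explicit diffusion is CFL-checked at construction.  The default
beat count is 20 — enough to pass the initial transient at these
kinetics and compare isoforms on the final beat; long-run protocols
(thousands of beats) use the same config with `n_beats` raised.

The extracellular potential at an axial electrode 2 cm beyond the
distal end is the discrete lead-field sum
Phi_e = (a^2 sigma_i / 4 sigma_e) * sum (−dVm/dx)(d(1/r)/dx) dx with
central differences inside, one-sided at the ends.  Conductivities and
fiber radius are not constrained by any shipped data; defaults
(sigma_i/sigma_e = 1, a = 11 um) make Phi_e arbitrary-unit, and only
shapes and intervals are interpreted.  The QT surrogate is the width
of the deflection complex: first departure from baseline beyond a
tolerance (2% of max deflection) to the last excursion beyond it —
used for orderings only.

### What the defaults produce

With the shipped M-model 1 parameters: APD90 decreases monotonically
with the hERG1b fraction, the open-state occupancy during
repolarization is higher for b-rich mixtures (faster activation and
recovery outweigh faster closing — the channels that deactivate
quickly also re-open quickly from the inactivated reservoir), and the
pure-b fiber's pseudo-ECG QT is several hundred ms shorter than
pure-a.  These are the orderings the tests assert; absolute APD/QT
values are properties of the surrogate and not claims about any
published cell model.

## Known limitations

* The M-model 2 parameter set, transcribed exactly as published,
  assigns the O <-> I pair voltage dependence of the opposite sign to
  M-model 1's (recovery slows, inactivation speeds up on
  hyperpolarization).  Simulated consequences: no recovery hook, a
  monotone rather than bell-shaped I-V, and an activation midpoint
  ordering between isoforms opposite to measurement.  The deactivation
  orderings do hold under M-model 2.  Quantitative claims
  (V1/2 targets, cell/tissue behavior) therefore rest on M-model 1
  throughout; M-model 2 is shipped for completeness and for its
  loop-closure machinery.
* Deactivation tau_fast at depolarized test voltages is not measurable
  by curve fitting for the a-isoform (component amplitude under 1%);
  use the eigenmode route for model comparisons.
* The surrogate cell has no calcium handling, no sodium-potassium
  pump, no restitution to speak of; it is a test vehicle for I_Kr
  coupling, not a predictive myocyte model.
* Temperature enters the conductance but not the shipped kinetics;
  physiological-temperature rate corrections must be supplied by the
  user as correction factors.
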