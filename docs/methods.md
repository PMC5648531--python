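# Methods

## Models

All three release models are first-order mass-action state networks
whose transition rates are either constant or linear in one of two
Ca²⁺ drives: the sensor-facing transient C(t) and the recruitment
drive Ca_rest + R(t) (residual Ca²⁺).  A scheme is stored as three
per-capita rate matrices (constant, C-linear, R-linear) plus a fusion
rate per state, recycling routing and zeroth-order influx terms; the
engine assembles the ODE right-hand side from these, so the
deterministic integrator and the stochastic simulator share one model
definition.

### Sequential two-pool model

States R₀, R₁ (reluctant pool) and V₀…V₅ (fully-releasable pool, the
index counting Ca²⁺ ions bound to the release sensor).

* Five-site cooperative sensor: the j-th ion binds at
  (5−j+1)·k_on·C(t) and unbinds at j·k_off·b^(j−1) with
  k_on = 1×10⁸ M⁻¹s⁻¹, k_off = 3000 s⁻¹, b = 0.25; fusion from V₅ at
  γ = 5000 s⁻¹.  The unbinding convention is the standard cooperative
  ladder (equilibrium occupancies
  w_j ∝ C(5,j)·(k_on·Ca/k_off)^j·b^(−j(j−1)/2), implemented in closed
  form as a test oracle).
* Recruitment: R₀→R₁ at k_prim·(Ca_rest + R(t)) with
  k_prim = 8×10⁸ M⁻¹s⁻¹, back at k_unprim = 120 s⁻¹; Ca²⁺-independent
  filling R₁⇌V₀ at k_fill = 200 s⁻¹ / k_unfil = 150 s⁻¹.  The
  reluctant↔releasable exchange is wired at the Ca²⁺-unoccupied sensor
  state V₀.
* Bookkeeping: 90% of the fusion flux is re-injected into R₀
  (instantaneous routing; no recycling delay is modelled), 10% is lost
  to an implicit recycling pathway and tracked in a cumulative "lost"
  channel.  A basal rate k_basal = 0.002 s⁻¹ refills R₀ from an
  implicit infinite reserve, by default as a constant influx
  (pool-units/s); a deficit-proportional variant
  k_basal·(R₀_rest − R₀) is selectable.  Occupancies are normalized so
  the resting fully-releasable pool sums to 1.

### Allosteric one-pool and parallel two-pool comparators

The one-pool model is a five-site ladder in which every state S_j fuses
at l₊·f^j.  Its rate constants are not constrained by the data this
package targets; the defaults are the canonical allosteric-sensor
values (k_on = 1×10⁸ M⁻¹s⁻¹, k_off = 4000 s⁻¹, b = 0.5,
l₊ = 2×10⁻⁴ s⁻¹, f = 31.3) and every one of them is config-exposed.
The pool (default 2000 vesicles, absolute counts) is reloaded into S₀
at a constant 2 SV/ms, independent of Ca²⁺.  The parallel model is the
disjoint union of a fast and a slow pool (default 1000 + 1000), the
slow pool identical except for a ten-fold smaller fusion scale
(J₊ = I₊/10; only the ordering J₊ < I₊ is constrained), each reloaded
at 2 SV/ms.

Two conventions here are deliberate:

* **Reloading is uncapped by default.**  A strictly constant
  replenishment rate means the pool grows between widely spaced
  stimuli; that overfilling is precisely why these models facilitate at
  low frequency and depress at high frequency (reload ≪ release per
  10 ms at 100 Hz).  Capping at the resting pool size (available via
  `reload_capped=True`, with a 0.1%-of-pool linear ramp to keep the
  right-hand side Lipschitz) pins the pool at rest and flattens the
  low-frequency response.
* **The comparators' sensors see the AP transient only.**  Residual
  Ca²⁺ is the recruitment signal of the sequential model's priming
  step; the comparator models have no Ca²⁺-dependent recruitment, and
  feeding the summed residual into their sensors (µM-level sustained
  Ca²⁺ against k_off = 4000 s⁻¹ and f = 31.3) generates a spurious
  strong facilitation at 100 Hz that misrepresents them.  For the
  sequential model the sensor defaults to rest + residual + AP
  (`CaParams.sensor_sees_residual`, flag exposed); the residual there
  is ≤ 2.5 µM and contributes a modest slow release component.

## Ca²⁺ waveforms

The sensor transient is a train of Gaussians (one per pulse) of
amplitude 22.5 µM on top of Ca_rest = 50 nM.  Residual Ca²⁺ adds
520 nM per pulse at the pulse time (no rise time is modelled) and
decays with τ = 42 ms, summing linearly; at 100 Hz the per-pulse peaks
follow the geometric series 520·(1−e^(−n·ISI/τ))/(1−e^(−ISI/τ)) nM,
reaching ≈ 2.45 µM at the 50th pulse, while at 2 Hz consecutive peaks
are equal to float precision.

**AP transient width (calibrated).**  The width of the local Ca²⁺
transient at the sensor is poorly constrained; microsecond-scale
transients of 22.5 µM amplitude are incompatible with this sensor: at
k_on = 1×10⁸ M⁻¹s⁻¹ a 5 µs half-width transient binds
k_on·amplitude·area ≈ 0.012 ions per site per AP, giving a single-AP
release probability of ~3×10⁻⁴ — no measurable evoked release, no pool
depletion, no short-term plasticity.  The default full width at half
maximum is therefore calibrated, once, against the independently
reported vesicular release probability of ~0.25 per AP at this synapse
at 2.5 mM external Ca²⁺: on a 0.05 ms grid, ap_fwhm = 0.55 ms gives
p_r,1 = 0.247 (the realized value for a single AP from rest) and is
frozen as the default.  This single calibration also lands the model's
paired-pulse ratio at 100 Hz (2.61) close to the measured ~2.16
without further adjustment.

## Numerical integration

The timeline is segmented at pulse-window boundaries (±6σ of the AP
Gaussian, σ = FWHM/2.355), at pulse times (residual increments are
discontinuities), and at release-window ends.  Within pulse windows
LSODA runs with max_step = σ/3 so the transient is resolved; between
windows the sensor signal is the single decaying exponential
rest + residual and the step size is unconstrained.  Integration
starts one window *before* the first pulse so its rising flank is not
truncated.  Default tolerances rtol = 1×10⁻⁸, atol = 1×10⁻¹²; halving
both changes per-pulse release probabilities by < 10⁻⁸ relative on
50-pulse trains, far inside the 0.1% convergence requirement.  The
cumulative fused and lost fractions are carried as extra ODE channels,
so release probabilities are solved to integrator accuracy rather than
quadratured post hoc.  Occupancies dipping below
−max(100·atol, 10⁻⁹·scale) raise an invariant violation; smaller
excursions are clipped to zero at segment boundaries.

**Per-pulse release probability**: the fusion flux integrated over
[t_i, t_i + min(ISI_i, 10 ms)).  The 10 ms window is one 100 Hz
inter-stimulus interval; phasic release completes well inside it.  By
this convention the release triggered on the *rising* flank of a pulse
falls into the preceding pulse's window at 100 Hz (windows tile the
train) and into no window at 2 Hz; the convention is applied uniformly,
and ratios (PPRs) are insensitive to it.

**Resting state.**  With the basal influx active the sequential scheme
has no steady state on simulation timescales (the influx slowly
overfills the pools over hours); with k_basal = 0 it has no nontrivial
fixed point at all, because the 10% non-recycled fusion leak drains
total mass at λ = 0.1·φ_rest/T ≈ 1.9×10⁻⁸ s⁻¹ (φ_rest ≈ 7.8×10⁻⁷ s⁻¹
is the rest-Ca²⁺ fusion flux through V₅, rate-limited by V₄→V₅
binding).  `resting_state` therefore returns the slowest-decaying
eigenmode of the k_basal-free generator, normalized to ΣV = 1: under
integration every state then decays uniformly by λt (≈ 2×10⁻⁶ per
100 s), which is the minimum drift any initialization can achieve.
Numerically this mode coincides with the flux-balance point
R₁/V₀ = k_unfil/k_fill, R₀/R₁ = k_unprim/(k_prim·Ca) with the ladder at
its (drain-corrected) equilibrium.  Allosteric schemes start at the
binding-ladder equilibrium over the pool size.

**Recovery restart.**  After the 2 Hz train the depression trajectory
is integrated 0.5 s past the last pulse (the delay at which recovery
trains are applied experimentally) so the millisecond-scale
recruitment transient has relaxed; the restart state then carries the
end values of the releasable total (placed in V₀ — between 2 Hz pulses
the sensor is unoccupied) and of R₁, sets R₀ to its fully recovered
resting value, and resets residual Ca²⁺.  R₁ is carried rather than
reset because a resting R₁ would refill V within ~10 ms
(k_fill·R₁_rest ≈ 150 s⁻¹) and erase the depressed first response the
restart exists to expose; both choices are overridable.  The first
recovery pulse follows one pulse window after the restart.

## Stochastic oracle

`gillespie_oracle` simulates the same CTMC exactly with time-varying
rates by thinning: candidate events are drawn at an upper bound on the
total propensity (Ca²⁺ evaluated at the AP peak inside pulse windows,
at the segment-start residual outside) and accepted with probability
actual/bound.  Vesicle counts are initialized multinomially with the
resting distribution over round(n_svs·T_rest) total vesicles, and the
result carries the implied mean initial releasable-pool size so
deterministic predictions can be scaled exactly.  Constant influx terms
are not simulated (runs use k_basal = 0), and the oracle is restricted
to ≤ 5 pulses and ≤ 100 vesicles.  The event loop is JIT-compiled with
numba; each repetition is seeded independently from the master seed,
so runs are bit-reproducible.

## EPSC-train analysis

* Fiber count: mean 0.033 Hz baseline amplitude / 5.3 pA (the median
  unitary EPSC including failures).
* Quanta per bouton: cumulative amplitude / (fiber count × 8 pA quantal
  content).  Boutons with two active zones cause a constant
  overestimation of the fiber count and hence underestimation of
  per-bouton quanta; since the bias is identical across stimulation
  paradigms it is documented, not corrected.
* LFD fit: normalized amplitude is modelled as a pre-onset level h for
  stimuli ≤ d, then p + (h−p)·exp(−(t−t_d)/τ); d is grid-searched
  (0…min(n/3, 40)) and (τ, p, h) fitted by bounded least squares in
  time for each candidate, smallest residual sum of squares winning.
  The reported plateau is p/h, the asymptote as a fraction of the
  initial level, and τ is in seconds.  The pre-onset level is *fitted*
  (nominally 1) because normalizing by the noisy first response shifts
  the entire curve by that response's noise; fixing h = 1 triples the
  change-point error at slow decays (median |d̂−d| 3 vs 1 stimuli at
  τ = 40 s, 5% noise).  The onset index d counts stimuli at baseline
  before the decay's first point, matching the synthetic generator's
  convention.  Trains whose tail median exceeds 0.8 of the initial
  level are flagged `no_depression`.
* Asynchronous-release check: max over stimuli of
  |charge/charge₁ − amplitude/amplitude₁|.  Proportional (purely
  synchronous) trains score 0; a slow charge component growing over the
  train pushes the score above the 0.1 flag threshold.

## Synthetic data

The generator emulates the statistical structure the analysis assumes:
per stimulus, each of n_fibers fibers releases an integer number of
quanta (Poisson by default; binomial over 5 docking sites, or the
deterministic expectation, selectable), each quantum contributes the
8 pA quantal content, and multiplicative Gaussian noise (default
CV 5%) models measurement error.  Baselines use 5.3 pA per fiber so
fiber-count estimation round-trips by construction — a modelling
convention mirroring the estimator's own definition, not a biological
claim.  Optional contamination adds a slow charge component as a
positive control for the superposition check.

What the generator does *not* emulate: raw current waveforms and
stimulus artifacts, bouton-to-bouton amplitude heterogeneity,
correlated (non-i.i.d.) trial variability, the ~12% of cells that show
no depression, and electrode/series-resistance effects.  Passing
round-trip tests therefore shows the estimators are correct and
well-calibrated under the stated statistical model, not that they are
robust to every feature of real recordings.

## Problem sizes in the test suite

The suite integrates the sequential model over the full 300-pulse 2 Hz
depression protocol and 50-pulse trains at 50/100 Hz, runs the
comparators over 50-pulse trains, checks the stochastic oracle at 20
vesicles × 3 pulses × 10⁴ repetitions, and runs the fit-recovery study
at 100 seeds per (τ, plateau) condition; the numbered analysis scripts
use 25 seeds per condition.  These sizes make the whole suite run in a
few minutes on one core while keeping Monte-Carlo standard errors well
below the tolerances tested.

## Known limitations

* With the printed rate constants the model's depression is slower and
  shallower than typical recordings: the 2 Hz decline reaches 16.7% of
  the first response after 300 pulses (measured plateaus ~14 ± 2%) with
  an effective decay constant of ~75 s (measured ~16 s).  The decline
  rate is fixed by mass balance — 10% of each cycle's fused vesicles
  (~0.27 of the releasable pool per pulse) leaves the recycling loop —
  so matching the measured τ would require a faster leak or more
  release per cycle than the stated parameters produce.
* Depression depth and between-pulse stability are coupled: any
  near-exponential decline reaching ≤ 15% in 300 pulses must shed
  ≥ 0.63% per pulse, so the releasable pool is already ~1.3% below rest
  by the third pulse.  "Full" relaxation between early low-frequency
  pulses holds only to that order.
* At rest the model refills the releasable pool from a recovered
  reluctant pool within tens of milliseconds; the minutes-long
  experimental recovery from depression is not captured (the implicit
  reserve and its slow dynamics are outside the model), which is why
  recovery is studied via the explicit restart procedure rather than by
  simulating rest periods.
* Spatial Ca²⁺ diffusion, buffering (e.g. EGTA) and channel gating are
  not modelled; the Ca²⁺ drives are imposed waveforms.
* The allosteric comparators' rate constants are transcribed defaults,
  not fits; conclusions about them are qualitative (sign structure),
  not quantitative.
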