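# Methods

## The circuit model

`antreg` models a cell that meets two environmental signals in a fixed
order within each growth cycle: s1 (a carbon source such as rhamnose) on
`[t0, t1)` and s2 (a stress such as paraquat) on `[t1, t2]`.  Each signal
reversibly activates a dedicated transcription factor,

    dRi*/dt = kf_i (Ri_total − Ri*) s_i(t) − kr_i Ri*,        i = 1, 2,

with conservation `Ri(free) + Ri* = Ri_total`.  The stress-response target
protein T2 is produced from a promoter with two saturating activation
terms and first-order turnover:

    dT2/dt = b1 R1*/(R1* + Km1) + b2 R2*/(R2* + Km2) − kd2 T2.

`b1 = 0` is the conventional wiring (each target controlled only by its
cognate regulator).  `b1 > 0` wires the first regulator onto the second
module's target — anticipatory (conditioned) regulation.  Each Km may be
written as `k_off / k_on` of the factor–DNA interaction.

Assumptions: regulator expression is constitutive (only activation is
signal-dependent); transcription and translation are lumped into one
production step; T1 dynamics are not modelled (fitness accounting involves
T2 only); the cell starts naive (`R1* = R2* = T2 = 0` at `t0`).  The
boundary instant `t1` is assigned to the s2 epoch (half-open convention);
the choice is arbitrary but fixed.

## Cost-benefit fitness

Benefit accrues only while s2 is present, at the saturating rate
`E(T2) = E_max · T2/(T2 + Km_T2)`; production carries a linear cost.  Net
fitness for one cycle is

    f = ∫_{t1}^{t2} E(T2) dt − cost over [t0, t2].

Protein made before t1 earns nothing — it can only pay off through the T2
that survives into the stress window.

Two cost accountings are implemented (`FitnessParams.cost_basis`):

* **synthesis** (default): c0 per unit of protein synthesized, i.e.
  `c0 ∫ P(t) dt` with P the production rate.  By the T2 equation this is
  exactly `c0 (T2(t2) − T2(t0) + kd2 ∫ T2 dt)`, which is how it is
  evaluated.  Under this accounting, holding a level of a fast-turnover
  protein is expensive (it must be continuously re-made), so pre-emptive
  expression becomes increasingly futile as kd2 grows.
* **abundance**: c0 per unit of standing protein per unit time,
  `c0 ∫ T2 dt`.

The synthesis basis is the default because it is the accounting under
which the three-regime structure exists at all.  A short marginal argument
shows why abundance cost cannot produce a storage-only (R1-only) regime:
at the R1-only interior optimum the benefit gradient per unit of
window-protein equals 1.5 c0 (the 1.5 is the ratio of the whole cycle to
the stress window for the default 6 h + 6 h timing), while a marginal
cognate contribution costs only c0 per unit — so switching on the cognate
term is always worth it, for every E_max, c0, Km_T2 and window split.
Under synthesis cost the comparison reverses at small kd2: protein stored
once before the window is made once, whereas cognate production must
synthesize its ramp inside the window, and the storage-only design wins.
Synthesis cost is also the only accounting under which the futile-window
cost grows with turnover, which is the mechanism that removes the storage
design at large kd2.

Both integrals use composite trapezoid quadrature on the simulation grid
(1001 points per signal segment by default); refining the grid changes the
result by < 1e-6 relative.

## Integration

The activation equations are linear within each signal epoch, so R*(t) is
closed-form there.  The default back end ("analytic") evaluates R*
exactly on a uniform per-segment grid and propagates T2 with an
exponential integrator (`T2[n+1] = e^{−kd2 h} T2[n] + w0 P[n] + w1
P[n+1]`) that is exact for piecewise-linear production input; its weights
are computed cancellation-free via `expm1`.  A stiff-capable adaptive
solver (`solve_ivp`, LSODA, rtol 1e-8 / atol 1e-10) is kept as the "ivp"
back end and cross-checked against the analytic one in the tests (they
agree to ~1e-5 absolute on the default grid).  Both restart the
integration at t1 so the forcing discontinuity is handled exactly.  Every
trajectory is checked for conservation (0 ≤ Ri* ≤ Ri_total) and
non-negativity.

## Default parameters

All model constants are package choices — the system is dimensionless and
no measured values exist for it.  Times are in the units of the signal
epochs (hours, by analogy with the 12 h transfer cycles of the emulated
experiment); concentrations and rates are arbitrary units.

| constant | default | why |
| --- | --- | --- |
| t0, t1, t2 | 0, 6, 12 | two equal 6 h epochs per 12 h cycle |
| s1, s2 levels | 1 | signal amplitudes absorb into kf |
| kf1 = kf2 | 1 | unit association rate |
| kr1 = kr2 | 4 | deactivation within ~15 min, fast against the 6 h epochs, so the regulator state tracks its signal; with slow dissociation (kr = 1) the first regulator keeps driving the target for hours into the stress epoch and the wiring designs blur together |
| R_total | 1 | conservation closure; only the product with kf matters |
| b windows | [0, 10] | zero included so "no regulation by R_i" is reachable |
| Km windows | [1e-2, 1e2] | four decades around R* scale |
| k_on window | [1e-2, 1e2], k_off = 1 | same Km span via Km = k_off/k_on |
| fixed b (binding mode) | 5 | mid-window strength when only affinities evolve |
| kd2 sweep | 25 log points on [1e-3, 10] | stable protein to ~7 min half-life |
| E_max | 5 (sweep grid [0.5, 10], 8 points) | benefit comparable to cycle length |
| Km_T2 | 1 | half-benefit at order-one protein level |
| c0 | 0.05 | production cost small against the benefit scale |

## Evolutionary search

A "mutation" multiplies one randomly chosen evolvable parameter by a
log-normal factor (scale `step = 0.4`) and clips it to its window; it is
fixed iff net fitness strictly increases.  Windows whose lower edge is 0
get a log-space floor at 1e-6 of the upper edge: proposals falling below
the floor snap to exactly 0, and a parameter at 0 re-enters at the floor
(zero-escape rule — otherwise 0 would be absorbing and a corner start
could never recruit the other regulator).  As the step size tends to 0,
mutations of positive parameters leave them unchanged.

Each optimization runs hill climbing from three deterministic archetype
starts (both terms at the geometric mid-window; each single-regulator
corner), any warm starts, and `restarts` random log-uniform starts, for
`iterations` mutations each.  The best point is refined by a deterministic
Nelder-Mead polish in log coordinates, and each promoter-gating term is
offered an exact-zero snap (a term polished to the floor is almost always
strictly better at exactly 0, where its residual synthesis cost vanishes).
Everything is driven by one seeded generator, so reruns are bitwise
identical.

Two evolvable sets mirror the two ways a promoter can rewire: promoter
strengths and thresholds (b1, b2, Km1, Km2), or binding on-rates (k_on1,
k_on2 with k_off fixed and promoter strengths held at `fixed_b`).

An optimum is classified by which promoter terms survive: a gating
parameter below 1e-3 of its upper window edge counts as absent, giving
R1_ONLY / ANTICIPATORY / R2_ONLY.  If both terms are absent (e.g. at zero
benefit) the label follows the larger term and a warning is raised.

Sweeps seed each grid point as `base_seed + index`, so they are
reproducible point-by-point.  At every point the reduced design (first
term pinned to its lower edge) is optimized first and its optimum warm
starts the full search; since the full design contains the reduced one and
the climb never accepts a worsening move, full ≥ reduced holds exactly at
every point by construction.  Regime sequences are majority-smoothed in a
centered window of 3 before band-structure assertions, to tolerate
isolated optimizer misses; the anticipatory window width of a sweep row is
the log10-kd extent of the longest contiguous anticipatory run plus one
grid spacing (half a cell on each side), so a single anticipatory cell has
width of one grid spacing.

An exhaustive log-grid search (≤ 4 dimensions, lexicographic tie-break)
serves as an independent oracle in the tests; the climber is required
never to fall below it.

Problem sizes used by the test suite and the acceptance script: 25-point
kd2 sweeps per mode, a 5 × 15 (E_max, kd2) map plus a 15-point zero-benefit
row, a 5-points-per-axis oracle on 10 random conditions, 100-seed rate
recovery, and 100 + 200 synthetic datasets for detection power and null
calibration.  These sizes resolve the band boundaries to the grid spacing
while keeping a full run in minutes.

## Growth-phenotype analysis

The Malthusian rate of a plate culture is `r = ln(OD_target/OD_init) /
t_cross`, with OD_init = 0.1 (the inoculation density), OD_target = 1.0,
and t_cross the first crossing of the target, interpolated linearly in
log-OD between the bracketing readings (exponential-growth assumption).
The estimator is a crossing-time summary, not a curve fit: on a noiseless
exponential it is exact for any sampling interval; on a logistic curve
with carrying capacity near the target it deliberately summarizes
sub-exponential growth (so it recovers the generative rate only while the
target OD is inside the exponential regime).  A curve that never reaches
the target raises an error carrying the maximum OD; rescaling all ODs and
both thresholds by a constant leaves r unchanged.

Group comparisons use a two-tailed t-test.  The default is the pooled
two-sample test (df = nA + nB − 2; triplicates give 4 df, matching how
such assays are conventionally reported); a paired test (df = n − 1) is
available.  Zero variance in both groups with equal means yields t = 0,
p = 1.  A line is called **anticipatory** iff its rhamnose-pre-exposed
mean rate exceeds the naive mean AND the two-tailed p-value is below
alpha.  Because the two-tailed p is gated on the biological direction, the
exact null rate of the verdict is alpha/2, not alpha; the calibration test
checks the plain rejection rate against alpha and the verdict rate against
alpha/2.  No multiple-testing correction is applied across lines —
verdicts are per line, mirroring how such panels are reported — so a
ten-line screen at alpha = 0.05 still carries a ~16% chance of at least
one false flag.

Promoter (reporter-fusion) activity is the mean over a time window of
blank-corrected fluorescence divided by blank-corrected OD, floored at 0;
a non-positive blank-corrected OD anywhere in the window is an error that
lists the offending times.

## Synthetic plate data

The generator emulates the *statistics* of the assay design, not its
biochemistry: ten lines (WT ancestor; Alt1-3 evolved under alternating
rhamnose/paraquat; Rha1-3 and PQ1-3 single-environment controls), two
pre-growth conditions, three replicates, 30-min sampling over 12 h,
inoculation OD 0.1.  Growth is logistic (capacity 2.0 OD) so plateau and
no-crossing edge cases arise naturally, with multiplicative log-normal
noise of mean exactly 1 (sd 0.02, proportional plate-reader error).
Baseline rates differ by line type (Alt/PQ 0.55 h⁻¹, WT 0.45, Rha 0.35 —
rhamnose-only lines grow slowest in paraquat).  The anticipatory phenotype
is a +20% relative rate effect applied only to Alt lines pre-exposed to
rhamnose; the reporter phenotype is a 3-fold induction of fluorescence per
OD (baseline 200 AU/OD, additive noise sd 5 floored at 0) applied only to
Alt lines in rhamnose.  Effect sizes and noise are package calibrations
chosen to make the qualitative pattern detectable at triplicate scale —
the emulated experiment reports its values only as figure bars.

What the generator does *not* emulate: lag and death phases, well position
effects, evaporation drift, between-day batch effects, condensation
artifacts, or any mechanistic coupling to the circuit model.  Passing the
detection tests therefore shows the pipeline is correct and calibrated
under proportional noise, not that real plates behave this ideally.

`generations_per_transfer(N) = log2(N)` converts a 1:N serial dilution to
doublings per cycle (1:100 → ~6.6).

## Numerical and degenerate-input choices

* Signal boundary: s1 active on `[t0, t1)`, s2 on `[t1, t2]`.
* Negative solver states beyond 100·atol abort integration; smaller
  undershoots clip to 0.
* Quadrature grids always contain t1 exactly (segment restart).
* Collapsed parameter windows (lo = hi) are legal and return the pinned
  point; an empty evolvable set is a configuration error.
* Grid-oracle ties break to the lexicographically smallest vector over
  sorted parameter names; zero lower edges contribute a literal 0 plus a
  log grid from 1e-4 of the upper edge.
* Non-monotone noisy OD curves use the first target crossing.

## Known limitations

* Deterministic ODEs only; no intrinsic expression noise (a cell-to-cell
  stochastic treatment could move the regime boundaries).
* Single-cycle fitness; repeated-cycle averaging is equivalent here
  because cycles are identical and the cell re-enters each cycle naive.
* Hill climbing with polish carries no global-optimality guarantee; the
  oracle bound and the archetype starts make misses rare but the regime
  maps tolerate isolated misses only through majority smoothing.
* The Hill exponent on the R1 term is configurable but defaults to 1;
  regime boundaries under cooperative activation were not explored.
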