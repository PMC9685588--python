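# Methods

This note documents the models and algorithms implemented in `autolc`,
the defaults and why they were chosen, what the virtual instrument does
and does not emulate, and the numerical choices that matter.

## Retention model and gradient retention times

Retention follows the linear-solvent-strength (LSS) law
`k(phi) = k0 * exp(-S * phi)`, with an optional quadratic extension
`k = k0 * exp(-S*phi + S2*phi**2)` for analytes whose log-retention is
visibly curved in the modifier fraction.  Under a programmed gradient
the analyte leaves the column at `tR = t0 + tau`, where `tau` solves the
migration integral `int_0^tau dt / k(phi_eff(t)) = t0` and `phi_eff` is
the pump program delayed by the dwell time `tD` (a pure delay: on-column
gradient deformation is not modeled).  Because the effective profile is
piecewise linear, the LSS integral has a closed form per piece
(`exp(S*a) * expm1(S*b*dt) / (k0*S*b)` on a ramp of slope `b`,
`dt / k(a)` on a hold) and the elution piece is inverted analytically
with `log1p`; no numerical quadrature is involved.  The quadratic law
uses composite 16-point Gauss–Legendre quadrature per ramp (subdivided
at 0.25 min) with Brent root-finding in the terminal piece.  Unit tests
hold the closed form against an independent adaptive-quadrature oracle
to 1e-6 min over 1000 random cases.

Every gradient program ends with a purge that steps the composition to
`phi = 1` — where `k` is finite — so elution always completes; a
degenerate all-zero program is an isocratic hold at `phi_1` that
collapses straight into the purge.

## Peak widths and plate numbers

Base widths (4 sigma) follow a plate-count model with optional gradient
peak compression: `w = 4*t0*(1 + k_e)*G / sqrt(N)`, where `k_e` is the
retention factor at the composition experienced at elution.  `G = 1` by
default — i.e., no compression — which deliberately over-predicts
widths; the classical LSS compression factor
`G = sqrt(1 + p + p^2/3)/(1 + p)` with `p = S*b*t0*k_e/(1 + k_e)` is
available by configuration.  Predicted widths are floored at **0.3 min**
at the base so the optimizer can never overestimate a separation; the
floor is configurable and never applied to simulated ground truth, which
makes the safety margin observable as a predicted-vs-achieved bias.

Plate numbers are fitted per analyte from scouting-run widths.  The
unfloored width model is linear in `1/sqrt(N)`, so the least-squares
minimizer is closed-form; `N` is clipped to [1e2, 1e7] and flagged when
it lands on a bound.  When every observed width sits at a known
reporting floor, `N` is unidentifiable from below and the flagged upper
bound is returned instead of a spurious estimate.

## Model fitting

Per analyte, 20 independent bounded L-BFGS-B minimizations of the sum of
squared retention-time residuals run from randomized starts (`log10 k0`
uniform on [-2, 6] — log-uniform in `k0` — and `S` uniform on
[0.5, 100]; `S2` on [-50, 50] for the quadratic law), each capped at
3000 objective evaluations; the lowest-SSE fit wins.  Fits from designs
with fewer distinct gradients than free parameters are flagged
ill-conditioned rather than rejected, and a large SSE per observation
sets a poor-fit flag.  Optimizing in `log10 k0` conditions the problem:
`k0` spans four decades while `S` spans one.

## Two-stage peak detection

Stage one detects local maxima on the baseline-corrected summed trace;
each is characterized by a local Gaussian fit (apex, 4-sigma base width,
area), falling back to half-height moments if the fit fails.  Stage two
uses only the m/z dimension: compute the time-averaged spectrum once,
then repeatedly take its most intense remaining channel, test that
channel's XIC for one or more genuine peaks, record any found with that
m/z, zero the channel, and stop once the removed channels describe more
than 80 % of the original spectrum area — or the current channel shows
no peak.  The 80 % threshold is exposed as configuration (it is a stop
rule, not a tuned constant).  The boundary is exclusive: a channel is
still investigated when the described area sits exactly at the
threshold.  With five equal-area channels the first four describe
exactly 80 %, so an inclusive boundary would silently skip the last
analyte — the exclusive reading is the one under which the rule does
what it says.

The peak-vs-noise test requires a local maximum at `min_snr = 10` times
the robust noise level with at least `min_points = 5` samples at half
height.  The noise level is `max(1.4826*MAD, (q75 - median)/0.674)`:
the second estimator stays calibrated when the detector clips noise at
zero (half the samples then sit exactly at zero and the MAD collapses).

Baseline correction is an asymmetric-penalty Whittaker smoother
(asymmetry `p = 0.001`, roughness `lambda = 1e5` calibrated at 2 Hz
sampling and rescaled by `(dt_ref/dt)^4` so the baseline's physical
smoothness is independent of the detector rate).  The retention-modeling
branch applies no baseline correction — peak detection there runs on raw
data; the smoother serves the BO branch's single-trace objective.

## Peak tracking

Peaks are grouped across runs by primary m/z within ±0.5 Th (greedy 1-d
chaining on a 1 Th centroid grid).  Within a group, each run's peaks are
aligned to the reference run — the run holding the most peaks of that
group, ties broken by run id so the result is independent of input
order — by an order-preserving minimum-displacement assignment
(Needleman–Wunsch dynamic program with a large gap cost, so peaks only
go unmatched when the counts force it).  Unmatched peaks become new
analytes.  Between retracks the tracker runs incrementally and searches
the new run only for analytes it already knows; the scheduled full
retrack (MDI 4, 9, 14, …) re-detects every stored run from scratch so
that compounds which only separate late in the optimization can still
enter the model.

## Objectives

With peaks sorted by retention time and `Rs = 2*dt/(w_a + w_b)` on base
widths, each adjacent `Rs` is capped at 2 and summed.  The resolution
score maps the capped sum onto [0, 1] (0 = every adjacent pair fully
resolved, 1 = total coelution); a chromatogram with one peak or none
scores 1, so an optimizer can never profit from losing peaks (the
convention for this degenerate case is ours).  The time score is
`min(t_last/t_max, 1)` and the performance score the weighted sum with
weights 1.00 and 0.05 — resolution dominates until it saturates.  The BO
branch additionally uses the number of connected components (peak
clusters chained by adjacent `Rs < 1.5`, plus separated peaks; a count
to maximize) and the product of adjacent resolutions.

## Candidate gradients and the two-stage optimizer

Candidates are 16-parameter, 5-segment programs (six compositions, five
holds, five ramps; the `phi = 1` purge and its 2-min hold are presets).
Random candidates draw six compositions uniformly and sort them, and
split an exponentially-distributed partition of a uniform fraction of
the 40-min budget over the ten times — monotone and budget-feasible by
construction.  Each MDI the pool holds exactly 2000 candidates: all
previously run programs plus fresh randoms.

Stage one refines every candidate against the resolution score alone
with Nelder–Mead over the raw 16-vector, capped at 500 evaluations;
feasibility is enforced by a projection repair inside the objective
(clip compositions to [0, 1] and sort; clip times at zero and rescale
into the budget, shaving one part in 1e12 so float rounding cannot
breach the inclusive boundary).  A candidate whose refinement ends worse
than it started keeps its original parameters.  The 200 best (ties:
shorter analysis, then pool order) enter a genetic algorithm on the
performance score: tournament selection of size 3, uniform crossover
with probability 0.7, per-gene Gaussian mutation (probability 0.1, sigma
5 % of each gene's range), elitism of 2, and the same repair after every
variation, for 1500 generations by default.  The GA's per-generation
mean and best-so-far fitness are recorded.  The objective kernel
(repair, migration integral, widths, score) is JIT-compiled; tests pin
it bit-for-bit against the scalar public API.

The loop stops when the achieved performance score improves by less than
1 % for two consecutive MDIs, or at 13 MDIs.  Stage one deliberately
ignores the time score — the time pressure enters in stage two.

## Bayesian-optimization strategy

Three-step gradients start at `phi_init = 0.05` held until
`t_init = 0.25 min`, pass through `(t_A, phi_A)` and `(t_B, phi_B)`, and
end at `phi_final = 1` at `t_final = 20 min` (all presets configurable).
The ordering constraints are enforced by reparameterization: the
surrogate works on the unit 4-box and each coordinate pair is sorted
before scaling, so every point is feasible.  The surrogate is a
Gaussian process with Matérn-5/2 kernel, constant mean, a small white
term, and normalized outputs; acquisition is expected improvement with a
scale-free exploration margin of 5 % of the observed objective range
(without it the search stalls on the plateaus of integer-valued
objectives), maximized over 4096 random feasible candidates with a
duplicate guard.  Initialization is a 3-point Latin hypercube.  A failed
surrogate fit falls back to a random feasible draw, with a warning.  The
BO branch never calls peak tracking or retention fitting.

## Virtual instrument

The generator draws, per analyte, `log10 k0` uniform on [0.5, 4] and `S`
uniform on [5, 40] coupled through a Gaussian copula at correlation 0.7
(in reversed-phase practice, strongly retained compounds respond more
steeply to the modifier), plate numbers uniform on [5e3, 5e4],
abundances log-uniform over two decades, and unique integer m/z
channels by default; an `overlapF` preset makes a fraction F of analytes
reuse another's channel to stress the tracker's order prior, and
multi-channel signatures are opt-in.  The default is one channel per
analyte because tracking identity is per-channel; a multi-channel
analyte is tracked as several consistent species, which is harmless to
the optimization but confounds analyte counting.

Rendering solves the true migration integral per analyte, draws a
Gaussian of the true (unfloored) width on each signature channel with
area = abundance × channel weight, and adds a slow baseline drift (2 %
of full scale, spread across channels), white detector noise, retention
jitter (sd 0.01 min) and width jitter (sd 2 %).  The detector noise
default is 1e-4 of full scale: apex intensities legitimately span about
three decades (two abundance decades times width variation), and modern
MS detectors resolve that; a coarser floor would simply hide the weak
half of the sample.  Acquisition covers the program, the purge, and any
stragglers still migrating at `phi = 1`, so the instrument and the
predictor agree that everything elutes.  The default grid is 10 Hz
sampling with 1 Th bins over 100–1500 Th; at 2 Hz the narrowest true
peaks (plate numbers up to 5e4 at `t0 = 1 min`) would span fewer than
the five samples the peak criterion requires and be invisible by
construction.

What the simulator does **not** emulate: peak tailing and fronting,
electrospray response and ionization suppression, isotope patterns and
charge states, carryover, on-column gradient deformation, and
column-temperature effects.  Passing tests therefore show that the
algorithms are internally consistent and recover known ground truth
under Gaussian-peak, linear-response conditions — not that they are
robust to every artifact of real LC–MS data.

## Numerical choices and degenerate inputs

* Budget and monotonicity boundaries are inclusive (`sum t <= t_max`,
  `phi_n <= phi_{n+1}`); validation reports violations as data, not
  exceptions.
* `expm1`/`log1p` keep the migration closed form accurate for nearly
  flat ramps; a ramp with `S*b*dt < 1e-14` is treated as a hold.
* Tracking tie-breaks are lexicographic (match cost, then run id);
  analyte ids order by consensus m/z then mean retention time, so
  re-tracking the same data reproduces identical tables.
* Empty chromatograms detect to empty peak lists; an empty peak set
  scores `o_rs = 1`, components 0, product 1 (empty product convention
  for n <= 1).
* All stochastic stages take explicit `numpy` generators; a master seed
  fans out per role (sample, instrument noise, candidate generation, GA,
  BO) through a hash, so any stage can be re-seeded independently and a
  run is exactly reproducible from (config, master seed).

## Problem sizes used in the test suite

Unit tests run at small scale (tens of candidates, tens of GA
generations, narrow m/z windows).  The end-to-end convergence check runs
the full 2000-candidate pool and top-200 selection with the GA scaled to
300 generations on a 30-analyte sample — the pool and selection sizes
are structural constants of the method, while the GA generation count
only trades polish for time, so it is the right knob to scale at desk
scale.

## Known limitations

* The Rs-based scores assume well-formed Gaussian peaks; heavily
  overlapped peaks merge at detection, so achieved scores are computed
  on what detection sees, exactly as on a real instrument.
* The incremental tracker drops unknown peaks between retracks by
  design; analytes detectable only under optimized gradients enter the
  model no earlier than the next scheduled retrack.
* The BO branch scales poorly beyond the four gradient parameters; the
  GA branch depends on tracking quality and inherits its failure modes.
* The quadratic retention law is fitted and predicted without a
  closed-form ramp integral, so it is noticeably slower inside the
  optimizers and intended for the scouting/fitting path.
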