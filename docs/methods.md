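# Methods

## Model and assumptions

The quantitative core is a linear unmixing of chiral-HPLC peak areas.
Two assumptions carry everything:

1. **Linearity per source and channel.**  A single source injected alone
   produces, on each stereoisomer channel it populates, a peak area
   linear in its concentration: `y_mi = a_mi·x_i + b_mi`, fitted by
   unweighted ordinary least squares over the standards.  Weighted or
   nonlinear calibration is deliberately out of scope; the reference
   curves report correlation above 0.999, so heteroscedasticity is a
   second-order effect at this precision.
2. **Additivity of areas.**  Stereoisomer peaks of different sources
   co-elute exactly, so an observed channel total is the sum of the
   per-source contributions: `S_m = Σ_i a_mi·x_i + k_m` with
   `k_m = Σ_i b_mi`, the sum running only over sources that have a
   calibrated curve on channel m (a source absent from a channel
   contributes neither slope nor intercept there).

With three stereoisomer channels the system `A·x = S − k` identifies at
most three sources; a fourth is rejected up front.  The packaged
three-source reference model has condition number ≈ 3.2, so area noise
is amplified only mildly into concentration error.

## Solvers and numerical choices

* **exact** (default): direct `numpy.linalg.solve` for n = 3,
  unconstrained least squares for n < 3.  Negative solved concentrations
  are physically impossible and indicate misfit; they are *reported and
  flagged*, never silently clamped.
* **nnls**: `scipy.optimize.nnls` on the same system, the opt-in
  constrained alternative for observations inconsistent with any
  non-negative composition.  Where the exact solution is already
  non-negative the two agree (tested property).
* Rank decisions use a relative singular-value cutoff of 1e-10; a
  rank-deficient system raises an identifiability error naming the
  colinear sources (read off the dominant components of the right
  null-space vector).
* Channels are always ordered by elution, sources by declaration order;
  permuting the declaration order permutes the solution identically.
* Replicates: the default solves on mean areas (matching how validation
  tables are printed); `solve_per_replicate` is the alternative and, the
  model being linear, its mean equals the mean-area solve.

## Tunable parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| presence threshold | 5 | µg/mL | lower end of the analytical range; below it a solved amount is indistinguishable from calibration error, so the source is called absent.  No published decision rule exists; this is the package's own choice and is configurable. |
| analytical range | 5–100 | µg/mL | stated validity range of the reference calibration; solutions outside it are still reported, with a warning flag per source. |
| calibration QC threshold | 0.999 | r² | matches the reported quality of the reference curves; advisory warning only, never blocking. |
| rank tolerance | 1e-10 | relative σ | standard double-precision cutoff, far below any chemically plausible colinearity. |

## Synthetic data: what it emulates, what it does not

No instrument dataset accompanies the reference model (its raw standard
injections were never published), so the `synthetic` module generates
every input the pipeline consumes:

* **Standards** follow the calibration line with Gaussian noise of
  standard deviation `cv·|mean area|`, truncated at zero (areas cannot
  be negative).  Only means ± SDs of replicate areas are published, with
  no distributional claim; Gaussian-with-CV is the minimal model
  consistent with them.
* **Mixtures** add the same channel-wise noise to the forward prediction
  `A·x + k`, per replicate.  The default CVs are computed at runtime
  from the packaged verification table (mean SD/mean per channel across
  its seven mixtures, ≈ 1.7–3.4%, within the 1–8% per-row spread), so
  simulations reproduce the replicate scatter of the real validation
  experiment.
* **Chromatograms** are Gaussian peaks at the three retention times
  (10.23, 11.81, 13.64 min), width σ = 0.15 min and 10 Hz sampling by
  default — chosen so adjacent peaks (≥ 1.58 min apart) are baseline
  resolved, as on the real column.  Peak height is set so the analytic
  area (height·60σ·√(2π), in mAU·s) equals the requested channel area.
  Integration is trapezoidal over per-channel windows (±4σ by default)
  with a straight-line baseline between window endpoints — the simplest
  defensible baseline; the real instrument's algorithm is unknown.

Not emulated: detector physics, peak tailing/asymmetry, retention drift,
cis/trans geometrical isomers, and the separation of injection vs.
preparation variance (the published SDs lump them, so the simulator
does too).  Passing tests therefore demonstrate correctness of the
calibration → assembly → solve → verify chain under the stated noise
model, not robustness to instrument artifacts the model excludes.

All simulation is driven by `numpy.random.default_rng` seeded through
`NoiseSpec`/`SeedSequence`, making every stochastic test and experiment
bit-reproducible.

## Degenerate inputs and edge cases

Fewer than two distinct standard concentrations is a degenerate-design
error; a constant response fits slope 0 with r² stored as an explicit
"undefined" flag (`None`), not NaN.  All-zero fingerprints, zero-area
ratio denominators, negative concentrations, overlapping integration
windows and out-of-span windows are rejected with typed errors.  An
observed composition with no non-negative solution keeps the exact
(negative, flagged) solution available for diagnosis alongside the nnls
alternative.

## Known limitations

* Ratios such as "15:1" or "1:2:1" are treated as descriptions; the
  packaged single-source areas give 14.1:1 and 2.88:1 and the continuous
  values are authoritative.
* The replicate-level extremes of recovery cannot be reproduced from
  mean-area tables: solving the packaged mean areas gives per-mixture
  yeast recoveries spanning only ~94–104%, so any reported extreme
  below that band must originate in unpublished per-replicate data.
  The acceptance suite asserts the band rather than the extreme.
* Errors-in-variables effects (noise in the calibration slopes
  themselves) are ignored: slopes are treated as known constants when
  solving, consistent with standard calibration practice at r² > 0.999.

## Problem sizes in the test suite

Property tests use 200–1000 random 3×3 systems and Monte-Carlo checks
use 500 replicate draws at the reference noise level — enough for
sub-percent standard errors on the asserted recovery bands while keeping
the whole suite under a few seconds.
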