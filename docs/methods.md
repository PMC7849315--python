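# Methods

`rootzone` models how the nitrogen source (ammonium vs nitrate) reshapes
growth of the *Arabidopsis thaliana* root tip through polar auxin
transport. It couples a mechanistic multicellular model, a Bayesian
calibration layer, and a synthetic-data generator that emulates the
study's measurement types, so the whole pipeline is testable without any
external data.

## The multicellular model

Two parallel ordered cell files — epidermis and cortex — are simulated,
indexed outward from the quiescent centre (QC), with `window` (default
40) cells each. Each cell carries five quantities: auxin amount `A`
(arbitrary units, a.u.), cytoplasmic PIN2 `PINc`, membrane PIN2 per face
`PINm` (apical = shootward, basal = rootward, plus the two lateral
faces), a division factor `DIV`, and length `L` (µm). Time is in model
units; the carrier transport normalization `k_a = 1` fixes the scale
(about one hour per unit, judged from the growth rate `k_l = 0.3`).

Per cell, between discrete events:

- **Auxin.** `dA_i/dt = s(i) + Σ_walls k_a (A_j·PINm_{j→i} −
  A_i·PINm_{i→j}) + k_d (A_lat − A_i) − d_a A_i`. Only the epidermis has
  a source `s(i)`: in the default two-rate variant, `s1` below the
  switch index `z` (QC-proximal production) and `s2` at or above it
  (influx forced in from the lateral root cap). The cortex receives no
  source. Carrier flux through a wall is proportional to the auxin of
  the donor cell and its PIN2 on that wall; flux through the epidermal
  outer (soil-facing) face is simply removed from the system.
- **Cytoplasmic PIN2.** `dPINc/dt = m_p − d_p PINc (1 + A/q_p) − T`,
  with synthesis `m_p`, basal turnover `d_p` enhanced linearly by auxin
  on the scale `q_p`, and trafficking outflow `T`.
- **Trafficking.** `T = PINc [N·tr_n + (1−N)·tr_wn] ·
  logistic(tr_a A + tr_i i)`, where `N ∈ {0,1}` is the binary nitrate
  indicator. A fraction `l_n·N` of delivered protein goes to the lateral
  face, the rest to the apical face; the basal face is unused (PIN2 is
  apically polarized in both files). Membrane pools decay at the same
  auxin-enhanced rate `d_p (1 + A/q_p)`.
- **Division factor.** `dDIV/dt = k_v0 k_v1 (A/maxA + L/maxL) /
  (1 + e^{i·t_v}) − DIV · k_v2 (1 + (A/k_v3)^{h1}) / (1 + (A/k_v4)^{h2})`
  — position-gated synthesis promoted by auxin and size, with
  auxin-modulated first-order decay.
- **Growth.** `dL/dt = k_l · A/(A+1) · L (1 − L/m_l)` — auxin-gated
  logistic growth toward the zone-dependent maximum length.

Events, applied in order each step: **transition** (a meristematic cell
enters the elongation zone, irreversibly, when its *relative auxin*
`A/maxA` reaches the regime-dependent threshold `A_thr`), **division**
(a meristematic cell with `DIV ≥ DIV_thr` and `L ≥ min_div_length`
splits into two daughters that each take half of every amount, with
`DIV` reset), and **window advection** (cells pushed past the window are
dropped, their auxin booked to the ledger).

Default parameter values are the published posterior means (`s1 = 8.36`,
`s2 = 22.53`, `z = 10.6`, `m_p = 30.49`, `d_p = 0.065`, `q_p = 100`,
`l_n = 0.60`, `tr_n = 0.246`, `tr_wn = 0.13`, `tr_a = −0.05`,
`tr_i = 0.30`, division constants `k_v0..k_v4, t_v, h1, h2` from the
prior root-meristem model they were adopted from, `k_l = 0.3`,
`m_l = 200` µm, and the ratio `d_a/k_a = 0.018`, realized as `k_a = 1`,
`d_a = 0.018`).

### Wall topology and the lateral coupling

The printed equations leave the epidermis→cortex coupling open, yet the
phenomena the model must reproduce require it: the cortex has no auxin
source of its own, so without an incoming lateral path cortex cells
could never grow, divide in an auxin-dependent way, or elongate — in
particular no regime could synchronize the two files. The package
therefore makes two topology choices, as its own design:

1. **Each file's lateral PIN2 face abuts the neighbouring file**: the
   cortex lateral face is its outer face (toward the epidermis) and the
   epidermal lateral face is its inner face (toward the cortex). Under
   nitrate, `l_n = 0.6` of trafficked PIN2 is lateral in both files, so
   the files exchange auxin bidirectionally through carriers — this is
   what synchronizes their elongation. The epidermal *outer* face (root
   surface) remains an external sink; nothing is trafficked there by
   default, but any PIN2 placed on it pumps auxin out of the system.
2. **A passive lateral wall permeability `k_d`** (default 30 /time,
   roughly 10–20% of the carrier conductance `k_a·PINm`) couples the
   files regardless of regime. On ammonium, where `l_n·N = 0` leaves no
   lateral carrier at all, this is the only path into the cortex; it
   sets how many cells later than the epidermis the ammonium cortex
   elongates. `k_d` was chosen during model construction so that the
   ammonium cortex elongates a few cells after the epidermis (as
   observed) rather than not at all (`k_d → 0`) or simultaneously
   (`k_d` large); it is deliberately regime-independent, so every
   nitrogen effect still flows through the trafficking terms.

### Normalizations

- `maxA` in the division-factor equation is the current maximum auxin
  over meristematic cells of both files (recomputed each step;
  a fixed-value override is available via `maxA_mode`). `maxL` defaults
  to `m_l = 200` µm.
- The *relative auxin level* used by the elongation threshold and by all
  reported profiles is `A` divided by the maximum over all window cells
  of both files. Normalizing by the meristem-only maximum would make the
  transition rule self-defeating: the largest meristematic cell always
  has ratio 1 and the whole meristem would cascade into elongation.
  The window-max normalization mirrors the per-root normalization of the
  ratiometric auxin reporter.
- Model predictions of reporter profiles (used by inference) are
  normalized per tissue file over the measured positions 1–20;
  synthetic reporter data are normalized per root across both tissue
  profiles jointly (one normalization constant per root), which is what
  preserves the between-tissue amplitude contrast present in the data.

### Calibrated artifact constants

The printed model omits the elongation thresholds and the division
trigger. They live in `rootzone/config/thresholds.yaml`
(regenerated by `scripts/calibrate_thresholds.py`, exposed as
`rootzone calibrate-thresholds`):

| constant | default | role |
| --- | --- | --- |
| `A_thr_ammonium` | 0.3466 | relative-auxin elongation threshold, N=0 |
| `A_thr_nitrate` | 0.5015 | same for N=1 (higher: more auxin needed on nitrate) |
| `A_min_transition` | 0.05 a.u. | absolute guard; keeps the near-uniform trace profile of the first instants from triggering transitions |
| `DIV_thr` | 5.0 | division-factor threshold for mitosis |
| `min_div_length` | 7.0 µm | daughters must regrow before dividing again |
| `k_d` | 30 /time | passive lateral wall permeability |

`A_thr_*` are calibrated by bisection on the full dynamic model so that
the time-averaged epidermal elongation onset sits at cell 11 on ammonium
and cell 13 on nitrate — the experimentally observed onsets. `DIV_thr`
and `min_div_length` give a division cycle of ~25 time units (a
realistic root-meristem cell cycle at ~1 h per unit) and meristematic
cell lengths of 4–10 µm.

### Numerics

The carrier pools make the auxin equations stiff (effective decay rates
up to a few hundred per time unit), so integration uses explicit RK4
(Euler available for cross-checks) with an automatically chosen stable
step, `dt = 0.4/max_rate`, typically 1–3×10⁻³. The public single-`step`
API enforces `dt · max_rate < 0.5` and names the offending pool. The
inner loop is JIT-compiled (numba) and is cross-checked against the pure
numpy path to ~1e-12. Pools are clipped at zero after each step
(truncation-level undershoot only). A cumulative auxin ledger (source
input, degradation, outer-surface efflux, advection loss) is integrated
with the same RK4 stages, so mass balance closes to rounding (~1e-13
relative) at every step; divisions conserve amounts exactly.

Because the relative-auxin transition rule describes the developed root,
`run()` holds transitions off for the first 100 time units while the
naive initial state (uniform 10 µm meristematic cells, `PINc = m_p/d_p`,
everything else zero) establishes its auxin and PIN2 pattern.

**Steady-state detection.** With divisions active the system reaches a
*statistical* steady state — division and advection events recur
forever — so a strict pointwise criterion (relative pool change < 1e-6
over a 10-unit window) can never be met; it is applied only to
division-free configurations. Otherwise convergence is declared when
10-unit moving averages of summary pools (total auxin, meristem cell
count, onset index per file) change by < 0.1% between windows. Onset
indices at the dynamic steady state fluctuate by roughly ±1 cell around
their stationary means; calibration and the regime-contrast checks use
time-averaged onsets over the trailing 200 time units.

**The static-file fixed point.** Growth, division and zonation do not
feed back on the auxin/PIN2 subsystem, whose fixed point on a static
pair of files has a semi-closed form: given the auxin vector, all PIN2
pools are closed-form per cell; substituting them leaves an
80-dimensional fixed-point problem in auxin alone, solved by damped
Gauss–Seidel sweeps (JIT-compiled, ~0.5 ms) with a Newton fallback.
This fixed point is the model's prediction for the snapshot fluorescence
measurements (PIN2 face intensities, relative auxin) and is what the
likelihood evaluates; it agrees with the dynamic attractor to ~2% when
growth and division are frozen. The dynamic profiles differ from it
systematically where division dilution is fast (see *Findings*, below).

## Synthetic data

The generator defines the study conditions the pipeline is tested under:

- **Length profiles** (`generate_length_profiles`): flat-then-linear
  mean curves — baseline `L0 = 10` µm up to the elongation onset, linear
  rise beyond — with the per-cell increment solved in closed form so the
  *expected OLS slope over positions 10–20 equals the published slope*
  (3.32639 / 1.22033 / 1.70502 / 0.82342 µm/cell for ammonium epidermis
  / ammonium cortex / nitrate epidermis / nitrate cortex). Onsets: 11
  (ammonium) and 13 (nitrate) in the epidermis, as published; 14 and 13
  in the cortex, chosen for the observed ammonium asynchrony and nitrate
  synchrony. Noise is Gamma around the mean curve (shape 16, cv ≈ 25%,
  the distribution family identified for these data); 18 roots per
  condition, positions 1–20.
- **Reporter profiles** (`generate_r2d2_profiles`): Venus/Tomato pairs
  drawn so the per-root-normalized reciprocal ratio follows logistic
  relative-auxin ramps — on ammonium the epidermal ramp is earlier and
  steeper than the cortex ramp; on nitrate both tissues share one ramp.
- **PIN2 intensities** (`generate_pin2_profiles`): phenomenological
  apical/lateral face means per condition (nitrate: higher total, much
  higher lateral share).
- **Model-based observations** (`generate_model_observations`):
  subsystem steady-state predictions corrupted with multiplicative Gamma
  noise of chosen cv (default 5%); the basis of all recovery and
  model-comparison studies. Zero-mean faces (lateral PIN2 on ammonium)
  are reported at a detection floor of 1e-6 a.u., mimicking instrument
  background; the likelihood floors its predictions identically.

What the generator does *not* emulate: per-root correlated deviations
(each observation is independent given the mean curve), imaging
artefacts, segmentation error, or between-replicate batch effects.
Passing recovery tests therefore demonstrate internal consistency of the
pipeline under the assumed noise model, not robustness to the full error
structure of microscopy data.

## Inference

- **Likelihood.** Each observation is Gamma-distributed around the
  model's steady-state prediction for its (condition, tissue, position,
  measurement) cell, with one dispersion (shape) parameter per
  measurement type — free in the sampler, profiled by method of moments
  in the fast point estimators. Fits use the snapshot measurements
  (PIN2 intensities, relative auxin) by default; length profiles can be
  included (`include_lengths=True`) at the cost of a full dynamic run
  per likelihood evaluation.
- **Sampling.** Seeded adaptive random-walk Metropolis in transformed
  space (log for positive parameters, logit for `l_n`): ≥4 chains,
  global scale tuned toward 28% acceptance, proposal shape from the
  running covariance of the burn-in samples. Priors: half-normal with
  scale 3× the default value for positive parameters, uniform on [0,1]
  for `l_n`, normal for the sign-free `tr_a`. Split R-hat and ESS
  (via arviz) are attached to every posterior; violations (R-hat > 1.05,
  ESS < 100) are reported as warnings rather than errors.
- **Model comparison.** The pointwise log-likelihood matrix collected
  during sampling feeds PSIS-LOO: importance ratios `1/p(y_i|θ_s)` are
  Pareto-smoothed (arviz's `psislw`, the same smoothing as the standard
  `loo` implementation) and assembled into elpd, its standard error, and
  per-observation Pareto-k diagnostics; with fewer than 5 tail samples a
  plainly truncated importance-sampling fallback is used and flagged.
  PSIS-LOO agrees with brute-force exact leave-one-out on conjugate
  problems to < 0.01 elpd.
- **Recovery.** `recover_parameter` profiles one parameter by grid scan
  plus bounded refinement; it errors, naming the parameter, when the
  likelihood is flat (e.g. division-factor constants, which do not enter
  the subsystem observables).

### Identifiability findings

- `z` is **set-identified**: the likelihood changes only when `z`
  crosses an integer cell boundary, so its posterior is essentially flat
  on (10, 11] at the defaults — consistent with the published credible
  interval [8.39, 12.02] spanning several cells. Posterior contraction
  with sample size holds for point-identified parameters (e.g. `s1`
  given `s2`, `l_n`, `tr_n`) but not for `z`.
- The overall source scale is **weakly identified** from snapshot
  measurements alone: relative auxin is scale-free and PIN2 pools depend
  on auxin only through `1 + A/q_p` and the logistic, both nearly flat
  at the realized auxin levels. The `(s1, s2)` posterior therefore has a
  soft common-scale ridge (this is what the covariance-adaptive proposal
  is for); predictive quantities are insensitive to position along the
  ridge.

## Findings and limitations

- **Division dilution vs trafficking.** At the subsystem steady state,
  nitrate raises total membrane PIN2 in every cell (`tr_n ≈ 1.9×
  tr_wn`), matching the fluorescence contrast. In the *dynamic* steady
  state the whole-window PIN2 total nevertheless falls on nitrate:
  nitrate lengthens the meristem and raises the division rate (as
  observed in the division data), and halving of membrane pools at each
  division outpaces the higher trafficking. The package treats the
  subsystem steady state as the fluorescence-equivalent quantity;
  the dynamic reversal is an emergent prediction of this implementation,
  not a calibrated feature.
- **Through-flux is conservation-limited.** At steady state the total
  shootward auxin flux through the two files equals the integrated
  source minus losses and is therefore regime-independent; nitrate
  *redistributes* the stream (more of it through the cortex, less
  through the epidermal apical faces) and raises transport *capacity*
  (membrane PIN2), but cannot raise the steady through-flux itself. A
  tracer-style contrast (more transport on nitrate) is thus outside what
  this 1-D fixed-source model can reproduce at steady state.
- The `literal_equations` switch restores the printed equations exactly
  (no trafficking debit from the cytoplasm, no membrane decay); these
  are non-conservative — membrane PIN2 grows without bound — so the
  switch exists for comparison runs only, and the subsystem fixed point
  is undefined under it.
- The printed source states the LRC influx location as "cell number 20
  from the QC" in prose while the parameter table estimates
  `z = 10.6 [8.39, 12.02]`; the table value is used, and the
  contradiction is recorded here rather than silently resolved.
- Problem sizes used by the test suite and the acceptance script (10
  replicate generations of 18 roots for the slope targets; 20 noisy
  datasets of 5 roots for recovery; 500 draws × 2 chains for the
  scaled-down variant comparison; 500-time-unit dynamic runs averaged
  over the trailing 200 units for regime contrasts) are the package's
  own working sizes, chosen to keep every study deterministic-by-seed
  and desk-scale.
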