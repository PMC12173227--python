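# Methods

This note documents the models, estimators, numerical choices and known
limitations of `neqbrain`, in enough detail to reproduce or challenge any
number the package computes.

## The Hopf whole-brain model

Each region j is a Stuart–Landau oscillator in Cartesian coordinates
(x_j, y_j), coupled diffusively through a directed nonnegative matrix C
(entry (i, j): source i → target j):

    ẋ_j = (a_j − x_j² − y_j²) x_j − ω_j y_j + G Σ_i C_ij (x_i − x_j) + β η_j
    ẏ_j = (a_j − x_j² − y_j²) y_j + ω_j x_j + G Σ_i C_ij (y_i − y_j) + β η_j

* **a_j** (dimensionless, default −0.02): bifurcation parameter. Below
  zero the origin is a stable focus and the node produces noise-driven
  damped oscillations; above zero a limit cycle of radius √a appears.
* **ω_j** (rad/s): intrinsic angular frequency, estimated from data as
  the in-band periodogram peak (mean across panels), or drawn uniformly
  in 2π·[0.04, 0.07] by the synthetic generator — the slow hemodynamic
  band.
* **G** (default 1) and **β** (default 0.02): global coupling gain and
  additive noise amplitude. β is not critical for fitted quantities
  because covariances are normalized (z-scored scale), but sets the
  signal-to-noise of simulated panels.
* Integration: Euler–Maruyama, dt = 0.1 s, independent Gaussian noise per
  node and component scaled √dt, 200 s burn-in, x subsampled at the output
  TR. dt = 0.1 s resolves the 0.04–0.07 Hz dynamics with two orders of
  magnitude of margin; halving dt changes long-run variances by < 5%
  (tested). The stepping kernel is numba-compiled when available, with an
  identical numpy fallback; noise is pre-drawn in a fixed order, so
  output is bit-reproducible for a given seed.

**Stability.** With diffusive coupling and nonnegative weights the
linearization is unconditionally stable for a_j < 0: each row of the
x-block Jacobian has diagonal a_j − GΣ_i C_ij and off-diagonal sum
GΣ_i C_ij, so every Gershgorin disc lies in Re(λ) ≤ a_j < 0. The
stability guard in `build_linear_model` therefore only triggers for
a_j ≥ 0 (or externally supplied negative weights); it is kept as a
defensive invariant.

## Linear engine

Dropping the cubic terms at the origin yields a 2N-dimensional
Ornstein–Uhlenbeck process dX = AX dt + β dW. Its stationary covariance
solves the continuous Lyapunov equation AΣ + ΣAᵀ + β²I = 0 (solved by
`scipy.linalg.solve_continuous_lyapunov`, residual checked at 1e−6), and
the lagged covariance is ⟨x_i(t) x_j(t+τ)⟩ = [Σ expm(Aτ)ᵀ]_ij. Both are
reported on the z-scored scale (divided by the stationary standard
deviations) to match the empirical estimator. Closed forms for one node —
var(x) = β²/(2|a|) and normalized lagged autocovariance e^{aτ}cos(ωτ) —
agree with the engine to machine precision, and a 50 000-sample nonlinear
run at β = 0.01 matches the analytic covariances to < 0.05 max-entry
(< 0.011 in the acceptance run). The linearization bias grows with β
(the cubic term shifts the effective decay by ⟨r²⟩ ≈ β²/|2a|), which is
why the agreement check uses small β.

## Covariance targets and filtering

The empirical summary of a panel is its Pearson correlation matrix and
the lag-Δt covariance of z-scored signals over the T−Δt overlapping
samples; Δt defaults to one TR (the minimal causal lag). Band-pass
filtering (zero-phase Butterworth, order 2 per pass, 0.04–0.07 Hz) is
always used for intrinsic-frequency estimation, and optionally
(`filter_before_fit`) for the covariance targets.

For the synthetic cohorts the pipeline fits **unfiltered** covariances:
the generated panels are band-limited by construction, and the analytic
linear model describes the unfiltered process. Fitting filtered
covariances with an unfiltered model family leaves a model-mismatch error
floor roughly five times the sampling floor and visibly degrades weight
recovery (measured during development). For empirical-style recordings —
where the filter removes drift and out-of-band physiological power — the
flag restores the conventional filter-then-fit order; users fitting real
data should be aware that the γ threshold is only comparable within one
choice of this convention.

## gEC fitting

The delta rule updates every masked off-diagonal weight by the remaining
covariance discrepancy,

    w_ij ← clip(w_ij + ε·[(corr0_emp − corr0_mod) + (covlag_emp − covlag_mod)]_ij, 0, cap),

with ε = 1e−3, cap = 0.2, stopping when the relative error improvement
over 100 iterations falls below 1e−5 (or a configured budget). The cap
bounds the weights well inside the stable regime and fixes the scale on
which the asymmetry threshold γ lives; weights are nonnegative because
diffusive coupling with negative weights has no physical reading here.
The fit is deterministic (analytic covariances, no simulation in the
loop). Because the update is a heuristic rather than a gradient, the
error can drift upward after a warm start; the fit therefore returns the
best iterate, which also guarantees that a subject-level fit initialized
at its group's solution never ends worse than it began.

Cohorts are fitted hierarchically: per group, the subjects' covariances
are averaged entrywise and a group gEC is fitted from the structural
scaffold; each subject is then fitted from the group solution. The group
stage sees √n-reduced sampling noise and gives individual fits a
well-placed starting point.

**Recovery fidelity.** Against analytic covariances of a known random
masked coupling (N = 20, density 0.3, independently drawn directions) the
fit recovers masked weights at Pearson r ≈ 0.97–0.999. Strongly
hierarchical truths (coherent asymmetry knob κ ≥ 0.7) are recovered only
to r ≈ 0.88: the pointwise update converges to a nonzero-residual
compromise, consistent with the stagnating error curve this class of fits
is known for. Against noisy finite-T covariances, pair-level weight
recovery degrades further (sampling error ~1/√T per entry is amplified by
the ill-conditioned inverse problem), but *aggregate* quantities — the
asymmetry count, group orderings — transfer reliably.

## Asymmetry and its threshold

The asymmetry count is the number of unordered pairs with
|w_ij − w_ji| ≥ γ. The default γ = 0.12 matches the gEC weight scale of
fits to empirical-style recordings under the 0.2 weight cap. Synthetic
cohorts live on a different scale, so the pipeline can calibrate γ as the
largest value on a 0.005 grid at which every fitted gEC retains at least
one asymmetric pair — the same "all values at least non-zero" rule, made
explicit. One-ulp corrections are applied before conceding a grid step,
so exact-arithmetic cases land on the expected grid point.

## Irreversibility (arrow of time)

Forward lagged correlations r_f[i,j] = corr(x_i(t), x_j(t+Δt)) and their
time-reversed counterparts r_r are mapped through FS = ½ log(1 − r²)
(computed as log1p(−r²); |r| = 1 raises, naming the entry) and the index
is the mean over all N² entries of (FS_f − FS_r)². It is nonnegative,
exactly invariant under time reversal of the input, and zero in
expectation for reversible processes. The finite-sample floor scales like
1/T with a variance shrinking in N²; the pipeline therefore computes it
on freely simulated resting runs (default 5000 samples at desk scale, 10
runs per model) rather than runs truncated to the recording length —
simulation length is free, unlike recording length. Simulated panels are
used raw (z-scored internally): band-pass filtering inflates the floor by
smoothing and was measured to *reduce* group discriminability.

## State-transition perturbational complexity

A perturbation run switches one node's bifurcation parameter to +0.2 for
the whole 100-sample response window after a 100-sample baseline, in one
continuous integration. PCA axes are taken from the demeaned response
(regions as variables); the smallest k axes reaching 99% cumulative
variance define the state space, and the baseline is projected with the
response's mean and loadings. Per component, the number of state
transitions (NST) is the mean over reference samples of value changes
along the thresholded pairwise-distance rows, per sample; ε is scanned
over 10 log-spaced values between the 1st and 99th percentile of the
pooled distance distribution, and the component contributes
max(0, max_ε(NST_resp − 1.2·NST_base)) — but only if its response RMS
exceeds 1.1× its baseline RMS. The SNR gate and baseline weighting follow
the established state-transition PCI construction; without the gate,
most retained components are pure noise and the max-over-ε floor
accumulates a positive bias that swamps any signal. The total is scaled
by the response length. Absolute sfPCI values depend on the protocol
constants and are not comparable across configurations; only orderings
and correlations are used.

## Synthetic cohorts

A cohort shares one connected symmetric Erdős–Rényi mask (as real
subjects share one tractography-derived scaffold). Per subject and masked
pair, a base weight w ~ U(0.5, 1)·weight_scale is split
w_ij = w(1 + κu), w_ji = w(1 − κu) with u ~ U(0, 1) and the stronger
direction consistently pointing up the node ordering — a coherent
hierarchy. Coherence matters: randomly oriented pair asymmetries largely
cancel at network scale and generate almost no net probability flux.
Mass balance (w_ij + w_ji independent of κ) isolates directionality from
overall coupling strength. Defaults: 90 regions, TR 2 s, 1505 volumes
(the scale of an overnight-sleep fMRI session), density 0.3,
weight_scale 0.05 (maximally split weights stay under half the 0.2
fitting cap).

What the generator does **not** emulate: hemodynamic convolution,
measurement noise with spatial structure, head motion, lesioned anatomy,
inter-subject structural variability. Passing tests therefore show that
the pipeline recovers the mechanism it models — not that it would survive
every artifact of real recordings.

## Statistics

Permutation tests use the add-one estimator p = (1 + #{|stat_perm| ≥
|stat_obs|})/(n_perm + 1) (never zero, unbiased), 10 000 permutations by
default, two-sided via centering (rank-sum) or absolute correlation
(Spearman), mid-ranks for ties. Benjamini–Hochberg thresholds are
(α/m)·rank with the standard step-up rule. Cohen's d uses the pooled SD
and, for total n < 50, the Hedges-type factor 1 − 3/(4n − 9); descriptors
small/medium/large at |d| = 0.2/0.5/0.8. Both permutation tests hold
their nominal 5% level within [0.02, 0.09] over 200 null replicates
(checked in the acceptance suite).

## Desk-scale configuration and problem sizes

`desk_scale_config` sizes the cohort experiment for a single CPU: 20
regions, 10 subjects per group, 1500-sample panels, fits capped at 3000
iterations with a 1e−4 stall tolerance, 10 resting runs of 5000 samples
per model for irreversibility, and 2 perturbation runs per node for
sfPCI. The full-scale settings (90 regions, 100 runs per node) are plain
config values and scale linearly.

## A deliberate divergence: sfPCI under the balanced knob

Across every protocol and analysis variant explored during development
(sustained, pulsed and recovery-only perturbations; raw, filtered and
baseline-normalized windows; coupling scales 0.02–0.2; noise 0.005–0.05),
ground-truth models with *higher* balanced asymmetry produce slightly
**lower** state-transition complexity: holding pair mass fixed, asymmetry
makes the network more feedforward, and its perturbation response
concentrates in fewer above-noise directions. This is a genuine property
of the mass-conserving asymmetry knob, and it is the opposite of the
empirical across-subject correlation that motivates the index, where
asymmetry covaries with many other connectivity differences between
states of consciousness. The package reports the sfPCI faithfully; in
the synthetic mechanism experiment the asymmetry and irreversibility arms
reproduce strongly (effect sizes 1–2, positive correlation between them),
while the sfPCI arm does not separate the groups and its cross-metric
correlations are near zero or negative. The corresponding end-to-end test
is left failing rather than weakened, as an accurate statement of what
this generator shows.

## Known limitations

* The delta rule is not a gradient method; strongly asymmetric targets
  are fitted to a nonzero-residual compromise (see recovery fidelity).
* γ thresholds are convention-dependent (z-scored covariances,
  filter-before-fit choice, weight cap) and not transferable across
  configurations.
* Absolute irreversibility values contain a finite-T positive bias; only
  comparisons at matched T are meaningful.
* Linearization around the limit cycle (a > 0), delay coupling, and
  regionally heterogeneous G are out of scope.
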