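# neqbrain

Whole-brain models place each brain region on the edge of an oscillatory
instability and couple the regions through a connectivity matrix; fitted to
resting-state fMRI they become personalized generative models that can be
probed *in silico*. `neqbrain` implements a complete pipeline built on that
idea for studying **nonequilibrium brain dynamics and perturbational
complexity across states of consciousness**:

1. **Hopf network simulation** — each of N regions is a Stuart–Landau
   oscillator (the normal form of a supercritical Hopf bifurcation),

   ẋ_j = (a_j − x_j² − y_j²) x_j − ω_j y_j + G Σ_i C_ij (x_i − x_j) + β η_j(t),

   with bifurcation parameter a_j = −0.02 (noisy damped oscillations),
   intrinsic frequencies ω_j in the 0.04–0.07 Hz band, global coupling
   G = 1 and additive noise β, integrated by Euler–Maruyama.
2. **Generative effective connectivity (gEC)** — the directed coupling
   C_ij is inferred by matching the model's zero-lag and time-lagged
   covariances to a recording's, using the linearized model's analytic
   covariances (a Lyapunov equation and a matrix exponential) inside an
   iterative delta-rule update under a symmetric structural mask. Because
   the lagged covariance is asymmetric, C_ij ≠ C_ji: the fit recovers
   directionality.
3. **Nonequilibrium metrics** — the *asymmetry count* N = Σ_ij 1{|C_ij −
   C_ji| ≥ γ} / 2, and the *irreversibility* I = ⟨(FS_fwd − FS_rev)²⟩ with
   FS = ½ log(1 − r²) applied to forward and time-reversed lagged
   correlations (the arrow of time of the simulated dynamics).
4. **Simulated perturbational complexity (sfPCI)** — one node is pushed
   past its bifurcation (a_j → +0.2) in silico; the response window is
   decomposed into principal components covering 99% of its variance, and
   the index counts the excess of threshold-crossing state transitions in
   the response over the baseline, summed over components.
5. **Statistics** — permutation rank-sum tests, Benjamini–Hochberg
   correction, Cohen's d with a small-sample (Hedges-type) adjustment,
   and permutation Spearman correlations.

Because clinical resting-state cohorts are not publicly deposited, the
package ships a first-class **synthetic cohort generator**: ground-truth
networks whose directional asymmetry is set by a knob κ ∈ [0, 1] (balanced
w(1 ± κu) splits around shared pair weights, so κ changes directionality
but not total coupling mass), simulated into BOLD-like panels with the
group structure of a consciousness study (e.g. high-κ "wakeful" vs low-κ
"reduced-consciousness" models).

The package is aimed at computational-neuroscience researchers who want a
tested, reproducible reference implementation of this model-based
nonequilibrium analysis, or a sandbox for method development on ground
truths where the answer is known.

## Worked example

Generate a two-group synthetic cohort (6 "wake" subjects at κ = 0.8, 6
"deep" subjects at κ = 0.1, 16 regions, TR = 2 s), fit a gEC per subject,
and compute all three metrics plus the group statistics:

```python
from neqbrain import CohortSpec, GroupSpec, RunConfig, FitConfig, run_cohort

spec = CohortSpec(
    groups=(GroupSpec("wake", 6, 0.8, seed=1), GroupSpec("deep", 6, 0.1, seed=2)),
    n_regions=16, tr=2.0, n_samples=1200, mask_density=0.3,
    weight_scale=0.05, mask_seed=0,
)
config = RunConfig(
    cohort=spec,
    fit=FitConfig(max_iter=2000, stall_window=50, stall_tol=1e-4),
    n_sims_irreversibility=8, n_sims_pci_per_node=2,
    filter_before_fit=False, rest_sim_samples=4000,
    n_perm=2000, master_seed=0,
)
table, report = run_cohort(config)
```

On one CPU this takes under a minute and prints (abridged):

```
subject_id state_label  asymmetry_count  mean_irreversibility  mean_sfpci
   wake-00        wake                7              0.000063   35.846812
   wake-01        wake                6              0.000056   39.440687
   ...
   deep-05        deep                3              0.000040   40.423875

calibrated gamma: 0.03
      asymmetry: deep=4.17 wake=7     p=0.0200 d=-1.54 sig=True
irreversibility: deep=4.83e-05 wake=6.62e-05 p=0.0005 d=-1.03 sig=True
          sfpci: deep=38.4 wake=37.9  p=0.5117 d=+0.11 sig=False
asymmetry~irreversibility: Spearman r=+0.80 p=0.0030
```

Reading the numbers: the high-κ "wake" models are fitted with markedly
more asymmetric effective connectivity (7 vs 4.2 above-threshold pairs at
the calibrated γ = 0.03, Cohen's d = 1.54) and their simulated resting
dynamics are further from detailed balance (irreversibility 6.6×10⁻⁵ vs
4.8×10⁻⁵, d = 1.03); the two metrics correlate strongly across subjects
(Spearman r = 0.80). The sfPCI does **not** separate the groups under this
generator — with total coupling mass held fixed, extra asymmetry makes
the network more feedforward and its perturbation response slightly
*lower*-dimensional; see `docs/methods.md` for the analysis of this
deliberate, honestly-reported divergence from the motivating empirical
findings.

A command-line interface mirrors the stages
(`neqbrain synth | fit | metrics | stats | all`, YAML-configured); run
`neqbrain --help`.

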