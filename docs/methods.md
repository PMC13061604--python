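# Methods

`chaperotrack` analyses dual-colour single-particle tracking (SPT) data of
chaperone–client interactions — the TRiC/CCT chaperonin and its co-chaperone
prefoldin (PFD) engaging nascent chains and newly synthesized clients such as
β-actin — together with codon-resolved selective-ribosome-profiling
enrichment data. Because raw live-cell movies are not redistributable, every
analysis step is validated against synthetic data with exact ground truth;
this note documents the models, the defaults and the choices made where the
design was genuinely open.

## Particle-movie generator

`simulate.simulate_movie` produces two-channel spot/track tables emulating
TIRF SPT at 50-ms frames over 500-frame movies (both configurable):

- **Clients** (ribosomes, polysomes, or ribosome-tethered proteins) diffuse
  with coefficient `d_client` (default 0 µm²/s — tethered species are
  effectively immobile on this timescale) in a square field (default
  10 × 10 µm) with reflecting boundaries.
- **Chaperones** diffuse with `d_free` (default 1.0 µm²/s) when unbound.
  The study does not report free-chaperone diffusion coefficients, so this
  default is an assumption in the config, not a measured value.
- **Binding** is first-order within a capture radius: a free chaperone
  within `capture_radius` (default 0.3 µm) of an unoccupied client binds
  with per-frame probability 1 − e^(−k_on·Δt) (default k_on = 5 s⁻¹).
  This deliberately trades reaction–diffusion fidelity for controllable
  on/off event statistics, which is what the downstream analysis consumes.
- **Bound state**: the chaperone rides the client position plus a Gaussian
  offset (`jitter_bound`, default 0.05 µm). The bound dwell is drawn from a
  single-exponential or two-component mixture model and discretized by
  *ceiling* to the frame grid: an event covering part of a frame is counted
  as co-localized in that frame.
- **Visibility**: photobleaching and defocalization are merged into one
  per-frame survival probability (default 0.995); a spot that fails the
  draw disappears permanently. The analysis only sees visibility, not its
  cause, so the two mechanisms need not be distinguished.
- **Localization noise** (default σ = 0.02 µm) is added to emitted
  positions only; the ground-truth log stores exact positions, binding
  states and events.
- An optional **refractory period** (`refractory_frames`, default 0) keeps
  a chaperone from rebinding immediately after release. With first-order
  in-radius binding and no refractory period, a released chaperone sits
  inside the capture radius and immediately rebinds, which merges
  consecutive events; detection-fidelity tests therefore use a refractory
  configuration, while rebinding-statistics runs use short refractory times
  as the off-state duration control.

What the generator does **not** model: camera noise beyond Poisson shot
noise in the optional renderer, drift, chromatic offsets, 3-D motion and a
true TIRF depth dimension, and any mechanistic off-state confinement (the
study's "protective zone"); confined off states are emulated simply by a
small `d_free`. Passing tests therefore demonstrate correctness of the
analysis operations under controlled kinetics, not robustness to every
artefact of real movies.

## Spot detection and linking

Detection (optional; the pipeline accepts external spot tables) uses a
scale-normalized Laplacian-of-Gaussian filter with sub-pixel refinement by
quadratic interpolation around each local maximum. The quality threshold is
defined on this filter response; it is not numerically comparable to other
tools' quality scores.

Linking solves the frame-to-frame linear assignment problem with cost =
squared displacement, a non-linking alternative cost of
`linking_max_distance²` (default 0.5 µm), and a globally optimal one-to-one
assignment (`scipy.optimize.linear_sum_assignment`), never greedy matching.
With `max_frame_gap = 0` (the default used throughout) a missing detection
always terminates a track; `gap_close_max_distance` is retained in the
config for fidelity but is inert at that setting. Output order and track
numbering are deterministic (sorted by first frame, then position).

## Co-movement events

Two tracks interact while their distance is **strictly below 0.5 µm**; an
event is a maximal run of consecutive co-localized frames of length ≥ 10
frames (500 ms at 50-ms frames). Sub-threshold runs are non-specific
contacts and are discarded everywhere. A single ≥ 0.5 µm frame or a
tracking dropout ends a run. When a chaperone is within range of several
clients in one frame, only the nearest partner counts (one interaction per
molecule at a time). Events touching a track boundary are flagged
boundary-censored and retained by default (no censoring correction is
applied; a config switch can exclude them). Per-condition frequencies are
reported as total events divided by the number of cells.

## Dwell-time kinetics

Event durations t carry the 0.5-s minimum-duration threshold, so survival
analysis works on the shifted time t′ = t − t_min: S(t′) is the fraction of
shifted durations ≥ t′, evaluated at the sorted unique durations, giving
S(0) = 1 and making the amplitude-free models below well-posed. Two models
are fitted by constrained nonlinear least squares on the empirical survival
(multi-start over a τ/α grid; SSE tie-break toward the smaller τ₂;
convergence tolerance 1e−10 on the SSE):

  F(t′) = e^(−t′/τ)                       (single)
  F(t′) = α·e^(−t′/τ₁) + (1−α)·e^(−t′/τ₂),  τ₁ < τ₂    (two-component)

Because fitted fractions are conditional on surviving past the threshold,
synthetic recovery runs generate directly on t′ and add the offset.

**Frame-grid registration.** Durations are counted in whole frames
(ceiling), so the empirical survival at grid point k·dt equals the
continuous survival at (k−1)·dt. The fit therefore evaluates the model at
max(t′ − dt, 0). Without this registration the one-frame offset is absorbed
very unevenly by mixture parameters (the constraint that amplitudes sum
to 1 forces compensation through τ and α) and biases weakly separated
mixtures far beyond their sampling error; with it, recovery of all
reference parameter sets is unbiased. Raw analytic curves can be fitted
with registration 0 via `fit_survival_curve`.

**Model selection.** The two-component model is accepted only if (i) its R²
against the empirical survival is strictly higher than the single-component
fit's, (ii) the minority fraction min(α, 1−α) exceeds 5% (implemented
literally as a fraction bound — no additional test statistic is defined),
and (iii) the fitted lifetimes are resolvable, τ₂/τ₁ ≥ 2. The separation
guard is this package's own addition: a nested mixture almost always gains
R², and on effectively single-exponential data the extra component collapses
into an arbitrary split of one lifetime with a spuriously large minority
fraction; requiring two-fold separation returns the single-component fit in
exactly those cases (validated on τ = 1.0 vs 1.5 mixtures, which are
reported as single). The applied rule, with all three comparisons, is
recorded in every fit report.

An MLE-based exponential fit is not the reference path; least squares on
the 1 − CDF is. A case-resampling bootstrap (percentile intervals) is
available for uncertainty estimates.

**Chase curves** (signal vs time) are fitted with f = y0 + a·e^(−b·x) and
summarized by the half-time ln 2/b (flagged undefined when the amplitude or
rate is degenerate). For band-intensity data normalized to the initial
timepoint the fit constrains y0, a ≥ 0: intensities are non-negative, and
on 5-point designs the constraint removes the y0–b trade-off that otherwise
dominates the estimator variance. Synthetic chase recovery follows the
assay protocol: three replicates at 5% additive noise (relative to the
initial signal) are averaged, then fitted once.

## Diffusion and rebinding

Per-track mobility uses the time-averaged MSD; the diffusion coefficient is
slope/4 (2-D) of a straight line through the first 4 lags (the intercept
absorbs the localization-noise floor), and the anomalous exponent is the
log–log slope over the same lags. Tracks are classified stationary
(D < 0.02 µm²/s), sub-diffusive (α_exp < 0.7) or diffusive. The fit range
and both thresholds are declared analysis parameters — the source study
names the classes without numeric criteria — and they are echoed into every
report.

An on–off–on rebinding cycle is a pair of consecutive events between the
same chaperone and client separated by an off interval throughout which the
chaperone stays tracked; chaperones lost during the off interval are
counted separately as untrackable (a TIRF-depth effect in real data). The
off interval is summarized by its duration, peak distance from the client
(using the client's last seen position within the interval when its spot
blinks, re-identified within 0.3 µm) and its motion class. Summary
fractions are reported against both denominators: all trajectories and
trackable-off trajectories.

## Ribosome-profiling enrichment

Genes with mean **input** coverage < 0.5 reads/codon are excluded
(boundary kept at ≥; whether the original filter used input, IP or both
channels is not documented — input is the default, both are available).
Each codon position i is tested with a two-tailed Fisher's exact test on
[[IP_i, IP_total − IP_i], [input_i, input_total − input_i]] and scored by
the sample odds ratio. P values are Benjamini–Hochberg adjusted per gene by
default (the positional test family is the coding sequence; a
transcriptome-wide mode exists). Interactions are called as runs of ≥ 5
*consecutive* codons with adjusted p < 0.05 and OR > 1 — enrichment only,
never depletion. The +1 pseudocount enters only the exported plotting
profiles, never the tests. For profiling across whole genes the
hypergeometric pmf is evaluated for all positions at once via log-gamma
algebra; this is numerically identical (≤ 1e−10) to per-position
`scipy.stats.fisher_exact` and checked against exact rational enumeration
in the tests.

Two-chaperone comparisons report shared substrates (genes called in both),
onset order (fraction of shared genes where one chaperone's first called
codon is strictly upstream; ties counted separately) and codon overlap
(intersection over union of called codons, per gene and pooled).

## Count generator

Synthetic profiling counts are Poisson around the per-codon input depth by
default (negative binomial with dispersion φ, var = µ + φµ², optionally);
IP expectations are scaled by the fold factor inside each enrichment
window. The default depth of 20 reads/codon represents a well-covered gene;
power and false-discovery properties are assessed at that depth with
8-fold, 50-codon windows.

## Problem sizes and determinism

All randomness descends from one integer seed through
`numpy.random.SeedSequence`, giving bit-identical outputs per seed. Dwell
recovery runs use n = 5,000 events and report the median over 10 seeded
replicates — the replicate median stabilizes the weakly identified mixture
corner (the 0.9/2.4 s set has component separation < 3, where
single-replicate fraction estimates scatter by ±10 points or more). Movie
simulations in the test and analysis drivers use 4–10 particles per channel
over 200–500 frames and a handful of movies per condition; null
false-discovery suites use 100–200 genes of 300 codons. These sizes give
stable Monte-Carlo estimates at interactive runtimes.

## Known limitations

- The LAP tracker has no motion model and no split/merge handling; dense
  fields beyond ~1 spot/µm² will mislink.
- Survival fits assume at most two exponential components; more complex
  dwell distributions are absorbed into the closest two-component fit.
- The rebind detector requires the client identity (track id or spatial
  re-identification); it cannot credit rebinding to a different copy of
  the same molecular species.
- The chance-colocalization specificity bound is validated on static
  non-interacting configurations; diffusing decoys produce correlated
  co-localization runs whose analytic rate has no closed form here.
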