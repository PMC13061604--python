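# chaperotrack

Analysis pipeline for live-cell single-particle tracking (SPT) of
chaperone–client interactions, built around the TRiC/CCT chaperonin and its
co-chaperone prefoldin (PFD). In these experiments two molecular species
are imaged simultaneously in separate colour channels (a Halo/SNAP-tagged
chaperone and a labelled ribosome, mRNA or client protein); sustained
spatial coincidence of their trajectories defines a molecular interaction,
and the distribution of interaction durations encodes the binding kinetics.

The package covers the full quantitative chain:

- **simulate** — synthetic two-channel particle movies (Brownian motion,
  capture-radius binding, exponential-mixture dwell times, photobleaching,
  localization noise), dwell samples, chase curves and ribosome-profiling
  count tables, all with exact ground truth.
- **tracklink** — Laplacian-of-Gaussian spot detection and optimal
  frame-to-frame LAP linking (0.5 µm radius, no gap closing).
- **comove** — co-movement events: maximal runs of frames with inter-track
  distance < 0.5 µm lasting ≥ 10 frames (500 ms), per-cell event
  frequencies, event distance statistics.
- **dwellkin** — interaction-lifetime kinetics. The survival function
  (1 − CDF) of event durations is fitted by constrained least squares to
  F(t) = e^(−t/τ) and F(t) = α·e^(−t/τ₁) + (1−α)·e^(−t/τ₂); the mixture is
  accepted only with higher R², minority fraction > 5% and τ₂/τ₁ ≥ 2.
  Exponential-decay chase fits f = y0 + a·e^(−b·x) give half-times ln2/b.
- **motion** — time-averaged MSD, diffusion coefficient (slope/4 over the
  first 4 lags), anomalous exponent, stationary/sub-diffusive/diffusive
  classes, and on–off–on rebinding cycles with off-state confinement
  statistics.
- **riboenrich** — codon-resolved selective-ribosome-profiling enrichment:
  0.5 reads/codon coverage filter, per-position two-tailed Fisher's exact
  test with odds-ratio scores, Benjamini–Hochberg correction, ≥ 5-codon
  run calling, and two-chaperone onset/overlap comparisons.
- **pipeline / cli** — YAML-configured end-to-end runs with structured
  logging and seed-traceable reports
  (`chaperotrack run --config configs/run.yaml`).

The numbered scripts under `analysis/` narrate the study workflow: simulate
movie cohorts, track and extract events, refit every reference lifetime
model, analyse off-state mobility and rebinding, fit chase half-times, and
call profiling enrichments. Each writes its tables under `results/`.

## Worked example

Fit the two post-translational TRiC–actin lifetime components from
synthetic dwell times generated at the reference parameters
(τ₁ = 0.9 s at 44%, τ₂ = 2.4 s at 56%):

```python
from chaperotrack.simulate import DwellModel, simulate_dwell_sample
from chaperotrack.dwellkin import DwellSample, fit_survival, select_model

durations = simulate_dwell_sample(DwellModel(0.9, 2.4, 0.44), n=5000,
                                  t_min=0.5, dt=0.05, seed=3)
sample = DwellSample(durations, t_min=0.5, dt=0.05)
fit1 = fit_survival(sample, "single")
fit2 = fit_survival(sample, "two")
chosen = select_model(fit1, fit2)
print(chosen.model, round(fit2.tau1, 2), round(fit2.tau2, 2),
      round(1 - fit2.alpha, 2))
print(chosen.selection_rule)
```

prints

```
two 0.99 2.36 0.53
two-component accepted: R2 0.999937 > 0.995803, minority fraction 0.467 > 0.05, tau2/tau1 2.39 >= 2
```

i.e. the mixture is accepted and the recovered lifetimes (0.99 s, 2.36 s)
and long-lived fraction (53%) match the generating model: about half the
binding events are short probing contacts, the other half are the ~2.4-s
folding cycles in which the client is transiently encapsulated.

Running `python analysis/03_dwell_kinetics.py` repeats this recovery for
all eight reference chaperone–client conditions and writes
`results/dwell_recovery.csv`.

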