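"""Study conditions and recovery protocols for the chaperonin interaction study.

Reference kinetic parameters of the TRiC/prefoldin (PFD) system measured by
live-cell single-particle tracking: interaction-lifetime models for the
chaperone-client pairs analysed, and the chase-assay designs for actin
transit through TRiC and degradation of the folding-defective actin mutant.
These define the generative conditions under which the analysis pipeline is
validated: synthetic dwell samples / chase curves are drawn at these
parameters and pushed through the fitting pipeline to check self-consistent
recovery.
"""

from __future__ import annotations

import numpy as np

from .dwellkin import DwellSample, fit_decay, fit_survival, select_model
from .simulate import DwellModel, simulate_chase, simulate_dwell_sample

__all__ = [
    "DWELL_CONDITIONS",
    "CHASE_CONDITIONS",
    "TERNARY_LIFETIME_S",
    "recover_dwell_model",
    "recover_half_time",
]

# Interaction-lifetime models (seconds; alpha = fraction of the shorter
# component).  Mixture fractions refer to events surviving the 0.5-s
# observation threshold.
DWELL_CONDITIONS: dict[str, DwellModel] = {
    # chaperone-nascent chain interactions on translating ribosomes
    "nascent_chain": DwellModel(0.8),
    # co-translational TRiC binding to actin nascent chains
    "tric_actin_co": DwellModel(1.0),
    # post-translational TRiC-actin folding cycles
    "tric_actin_post": DwellModel(0.9, 2.4, 0.44),
    # post-translational PFD-actin (modulating vs retrieval modes)
    "pfd_actin_post": DwellModel(0.8, 4.9, 0.70),
    # TRiC on the folding-defective actin(G150P) mutant
    "tric_actin_g150p": DwellModel(3.8, 12.6, 0.78),
    # PFD on full-length nascent actin near termination (long mode 24%)
    "pfd_actin_full": DwellModel(1.0, 6.0, 0.76),
    # PFD-TRiC inter-chaperone contacts, basal conditions
    "pfd_tric_basal": DwellModel(0.9),
    # ternary PFD-TRiC-actin complex (actin-SunTag over-expression)
    "pfd_tric_ternary": DwellModel(0.7),
}

TERNARY_LIFETIME_S = 0.7   # PFD-TRiC-actin ternary complex lifetime

# Chase designs: (half_time, timepoints, unit).  Signals are band
# intensities normalized to 1 at t = 0 and decaying to 0.
CHASE_CONDITIONS: dict[str, dict] = {
    # actin transit through TRiC during a puromycin chase (timepoints in s)
    "actin_transit": {
        "half_time": 48.0,
        "timepoints": np.array([0.0, 0.3, 1.3, 2.3, 3.3, 5.3, 9.3]) * 60.0,
        "unit": "s",
    },
    # degradation of the mutant actin fusion during a cycloheximide chase
    # (timepoints in min)
    "g150p_degradation": {
        "half_time": 36.0,
        "timepoints": np.array([0.0, 30.0, 45.0, 60.0, 120.0]),
        "unit": "min",
    },
}


def recover_dwell_model(
    model: DwellModel,
    n: int = 5000,
    n_replicates: int = 10,
    seed: int = 0,
    t_min: float = 0.5,
    dt: float = 0.05,
) -> dict:
    """Generate-and-refit self-consistency run for one lifetime model.

    Draws ``n_replicates`` independent samples of ``n`` truncated,
    frame-discretized dwells, fits both survival models with the selection
    rule, and reports the median fitted parameters across replicates
    (replicate medians stabilize the weakly identified mixture corner).
    """
    ss = np.random.SeedSequence([seed, 424242])
    rep_seeds = [int(s % (2**31)) for s in ss.generate_state(n_replicates)]
    rows = {"tau": [], "tau1": [], "tau2": [], "alpha_long": [], "selected": []}
    for rs in rep_seeds:
        durations = simulate_dwell_sample(model, n, t_min=t_min, dt=dt, seed=rs)
        sample = DwellSample(durations, t_min=t_min, dt=dt)
        fit1 = fit_survival(sample, "single")
        fit2 = fit_survival(sample, "two")
        chosen = select_model(fit1, fit2)
        rows["selected"].append(chosen.model)
        rows["tau"].append(fit1.tau)
        rows["tau1"].append(fit2.tau1)
        rows["tau2"].append(fit2.tau2)
        rows["alpha_long"].append(1.0 - fit2.alpha)
    out = {
        "n": n,
        "n_replicates": n_replicates,
        "tau_hat": float(np.median(rows["tau"])),
        "tau1_hat": float(np.median(rows["tau1"])),
        "tau2_hat": float(np.median(rows["tau2"])),
        "alpha_long_hat": float(np.median(rows["alpha_long"])),
        "selected_models": rows["selected"],
        "majority_model": max(set(rows["selected"]), key=rows["selected"].count),
    }
    return out


def recover_half_time(
    half_time: float,
    timepoints: np.ndarray,
    n_replicates: int = 3,
    seed: int = 0,
    noise_frac: float = 0.05,
) -> dict:
    """Chase-assay recovery: average ``n_replicates`` noisy curves, fit once.

    The generated signal is y(t) = exp(−ln2·t/half_time) (normalized, fully
    decaying) with additive Gaussian noise of ``noise_frac`` of the initial
    signal per replicate; the replicate-averaged curve is fitted with
    non-negative baseline/amplitude and summarized by ln(2)/b.
    """
    b = float(np.log(2) / half_time)
    ss = np.random.SeedSequence([seed, 515151])
    rep_seeds = [int(s % (2**31)) for s in ss.generate_state(n_replicates)]
    curves = [
        simulate_chase(0.0, 1.0, b, timepoints, noise_sd=noise_frac, seed=rs)
        ["signal"].to_numpy()
        for rs in rep_seeds
    ]
    mean_curve = np.mean(curves, axis=0)
    fit = fit_decay(timepoints, mean_curve, nonneg=True)
    return {
        "half_time_hat": fit.half_time,
        "r_squared": fit.r_squared,
        "n_replicates": n_replicates,
        "fit": fit,
    }
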