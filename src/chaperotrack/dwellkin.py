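"""Interaction-lifetime kinetics: survival curves, exponential(-mixture) fits,
model selection, and exponential-decay chase fits.

The dwell-time distribution of chaperone-client interactions is modelled by
its survival function (1 − CDF).  Two models are fitted by constrained
nonlinear least squares on the empirical survival:

    single component:  F(t) = exp(−t/τ)
    two components:    F(t) = α·exp(−t/τ1) + (1−α)·exp(−t/τ2),   τ1 < τ2

The two-component model is accepted only if it has a higher coefficient of
determination (R²) than the single-component model AND both mixture
fractions exceed 5% — otherwise the single-component fit is kept.

Time origin: observed durations carry a minimum-duration threshold ``t_min``
(short contacts are discarded upstream), so survival is computed on the
shifted time t' = t − t_min.  Then S(0) = 1 and the amplitude-free models
above are well posed; for a memoryless (exponential) process the shift
leaves τ unchanged.  Fitted fractions therefore refer to the mixture
conditional on surviving past the threshold.

Chase assays (signal decaying over time) are fitted with
f(x) = y0 + a·exp(−b·x) and summarized by the half-time ln(2)/b.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import curve_fit, least_squares

__all__ = [
    "DwellSample",
    "SurvivalFit",
    "DecayFit",
    "empirical_survival",
    "fit_survival",
    "select_model",
    "fit_decay",
    "bootstrap_ci",
]

_SSE_TOL = 1e-10


@dataclass
class DwellSample:
    """Observed dwell durations (seconds), each >= t_min, on the dt grid."""

    durations: np.ndarray
    t_min: float = 0.5
    dt: float = 0.05
    censored: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.durations = np.asarray(self.durations, float)
        if self.durations.size < 1:
            raise ValueError("need at least one duration")
        if self.t_min < 0:
            raise ValueError("t_min must be >= 0")
        if np.any(self.durations < self.t_min - 1e-9):
            raise ValueError("all durations must be >= t_min")

    @property
    def n(self) -> int:
        return self.durations.size

    @property
    def shifted(self) -> np.ndarray:
        return self.durations - self.t_min


@dataclass
class SurvivalFit:
    model: Literal["single", "two"]
    tau: float | None = None          # single component
    tau1: float | None = None         # mixture, tau1 < tau2
    tau2: float | None = None
    alpha: float | None = None        # fraction of component 1 (shorter)
    r_squared: float = np.nan
    sse: float = np.nan
    n: int = 0
    converged: bool = True
    selected: bool = False
    selection_rule: str = ""
    registration: float = 0.0   # frame-grid registration used during fitting (s)
    curve_t: np.ndarray | None = field(default=None, repr=False)
    curve_s: np.ndarray | None = field(default=None, repr=False)

    def predict(self, t: np.ndarray) -> np.ndarray:
        """Continuous-model survival F(t)."""
        t = np.asarray(t, float)
        if self.model == "single":
            return np.exp(-t / self.tau)
        return self.alpha * np.exp(-t / self.tau1) + (1 - self.alpha) * np.exp(-t / self.tau2)

    def predict_observed(self, t: np.ndarray) -> np.ndarray:
        """Model survival registered to the observation grid, F(max(t - reg, 0))."""
        return self.predict(np.maximum(np.asarray(t, float) - self.registration, 0.0))


@dataclass
class DecayFit:
    y0: float
    a: float
    b: float
    half_time: float          # ln(2)/b; nan when flagged undefined
    r_squared: float
    valid: bool = True


def empirical_survival(sample: DwellSample) -> tuple[np.ndarray, np.ndarray]:
    """Empirical survival S(t') = fraction of shifted durations >= t'.

    Evaluated at the sorted unique shifted durations; S is non-increasing
    and S(0) = 1 (the smallest evaluation point includes every observation
    by the >= convention).
    """
    shifted = np.sort(sample.shifted)
    t_unique = np.unique(shifted)
    # count of durations >= t: n - (index of first element >= t)
    idx = np.searchsorted(shifted, t_unique, side="left")
    s = (sample.n - idx) / sample.n
    return t_unique, s


def _dist_mean(t: np.ndarray, s: np.ndarray) -> float:
    """Mean of the distribution underlying an empirical survival curve."""
    mass = s - np.append(s[1:], 0.0)
    return float(np.sum(t * mass))


def _fit_single(t: np.ndarray, s: np.ndarray,
                shift: float = 0.0) -> tuple[np.ndarray, float, bool]:
    te = np.maximum(t - shift, 0.0)
    mean = max(_dist_mean(t, s), 1e-6)
    best = None
    for tau0 in (0.5 * mean, mean, 2.0 * mean):
        try:
            res = least_squares(
                lambda p: np.exp(-te / p[0]) - s,
                x0=[tau0],
                bounds=([1e-9], [np.inf]),
                xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
        except Exception:
            continue
        sse = float(np.sum(res.fun**2))
        if best is None or sse < best[1] - _SSE_TOL:
            best = (res.x, sse, res.success)
    if best is None:
        return np.array([mean]), float("inf"), False
    return best


def _fit_two(t: np.ndarray, s: np.ndarray,
             shift: float = 0.0) -> tuple[np.ndarray, float, bool]:
    te = np.maximum(t - shift, 0.0)
    mean = max(_dist_mean(t, s), 1e-6)

    def resid(p):
        a, t1, t2 = p
        return a * np.exp(-te / t1) + (1 - a) * np.exp(-te / t2) - s

    best = None
    for f1 in (0.2, 0.5, 1.0):
        for f2 in (2.0, 5.0, 10.0):
            for a0 in (0.3, 0.5, 0.7):
                try:
                    res = least_squares(
                        resid,
                        x0=[a0, f1 * mean, f2 * mean],
                        bounds=([0.0, 1e-9, 1e-9], [1.0, np.inf, np.inf]),
                        xtol=1e-12, ftol=1e-12, gtol=1e-12,
                    )
                except Exception:
                    continue
                sse = float(np.sum(res.fun**2))
                # ties broken by smaller tau2 (after ordering)
                tau2 = max(res.x[1], res.x[2])
                if (best is None or sse < best[1] - _SSE_TOL
                        or (abs(sse - best[1]) <= _SSE_TOL and tau2 < best[3])):
                    best = (res.x, sse, res.success, tau2)
    if best is None:
        return np.array([0.5, 0.5 * mean, 2.0 * mean]), float("inf"), False
    return best[0], best[1], best[2]


def fit_survival(sample: DwellSample, model: Literal["single", "two"]) -> SurvivalFit:
    """Constrained least-squares fit of a survival model to a dwell sample.

    Minimizes Σ[S_emp(t'_i) − F(t'_i)]² over the sorted unique shifted
    durations, with τ > 0 (and 0 ≤ α ≤ 1 for the mixture; τ1 < τ2 enforced
    by reordering).  Multi-start initialization; deterministic given the
    sample.

    Frame-grid registration: durations are counted in whole frames (an event
    covering part of a frame counts that frame), so the empirical survival
    at grid point k·dt — with the >= convention — equals the continuous
    survival at (k−1)·dt.  The model is therefore evaluated at
    max(t' − dt, 0); without this the one-frame offset systematically skews
    mixture parameters.  Fit raw (t, s) curves with
    :func:`fit_survival_curve` and ``registration=0`` instead.
    """
    import warnings

    min_n = 10 if model == "single" else 50
    if sample.n < min_n:
        warnings.warn(
            f"{model}-component fit on n={sample.n} < {min_n}: best-effort result",
            stacklevel=2,
        )
    t, s = empirical_survival(sample)
    return fit_survival_curve(t, s, model, registration=sample.dt, n=sample.n)


def fit_survival_curve(
    t: np.ndarray,
    s: np.ndarray,
    model: Literal["single", "two"],
    registration: float = 0.0,
    n: int = 0,
) -> SurvivalFit:
    """Fit a survival model to an explicit (t', S) curve."""
    t = np.asarray(t, float)
    s = np.asarray(s, float)
    if model == "single":
        params, sse, ok = _fit_single(t, s, shift=registration)
        fit = SurvivalFit(model="single", tau=float(params[0]), n=n,
                          converged=bool(ok), registration=registration)
    else:
        params, sse, ok = _fit_two(t, s, shift=registration)
        a, t1, t2 = float(params[0]), float(params[1]), float(params[2])
        if t1 > t2:
            t1, t2 = t2, t1
            a = 1.0 - a
        fit = SurvivalFit(model="two", tau1=t1, tau2=t2, alpha=a, n=n,
                          converged=bool(ok), registration=registration)
    pred = fit.predict_observed(t)
    ss_tot = float(np.sum((s - s.mean()) ** 2))
    fit.sse = float(np.sum((s - pred) ** 2))
    fit.r_squared = 1.0 - fit.sse / ss_tot if ss_tot > 0 else (1.0 if fit.sse == 0 else np.nan)
    fit.curve_t, fit.curve_s = t, pred
    return fit


def select_model(fit1: SurvivalFit, fit2: SurvivalFit,
                 min_tau_ratio: float = 2.0) -> SurvivalFit:
    """Apply the acceptance rule between a single- and a two-component fit.

    The two-component fit wins iff its R² is strictly higher AND the minority
    fraction min(α, 1−α) exceeds 0.05; otherwise the single-component fit is
    returned.  A separation guard is applied on top: when the fitted
    lifetimes differ by less than ``min_tau_ratio`` the mixture is treated
    as unresolved (such fits are unstable — two nearly equal lifetimes can
    split an effectively single-exponential decay arbitrarily) and the
    single-component fit is kept.  The applied rule is recorded on the
    returned fit.
    """
    if fit1.model != "single" or fit2.model != "two":
        raise ValueError("expected (single, two) fits in that order")
    minority = min(fit2.alpha, 1.0 - fit2.alpha)
    better = fit2.r_squared > fit1.r_squared
    significant = minority > 0.05
    separated = fit2.tau2 >= min_tau_ratio * fit2.tau1
    if better and significant and separated and fit2.converged:
        chosen = fit2
        rule = (f"two-component accepted: R2 {fit2.r_squared:.6f} > "
                f"{fit1.r_squared:.6f}, minority fraction {minority:.3f} > 0.05, "
                f"tau2/tau1 {fit2.tau2 / fit2.tau1:.2f} >= {min_tau_ratio:g}")
    else:
        chosen = fit1
        reasons = []
        if not better:
            reasons.append(f"R2 {fit2.r_squared:.6f} <= {fit1.r_squared:.6f}")
        if not significant:
            reasons.append(f"minority fraction {minority:.3f} <= 0.05")
        if not separated:
            reasons.append(
                f"lifetimes unresolved (tau2/tau1 {fit2.tau2 / fit2.tau1:.2f}"
                f" < {min_tau_ratio:g})")
        if not fit2.converged:
            reasons.append("two-component fit did not converge")
        rule = "single-component kept: " + "; ".join(reasons)
    chosen.selected = True
    chosen.selection_rule = rule
    return chosen


def fit_dwell_sample(sample: DwellSample) -> SurvivalFit:
    """Convenience: fit both models and apply the selection rule."""
    return select_model(fit_survival(sample, "single"), fit_survival(sample, "two"))


def fit_decay(time: Sequence[float], signal: Sequence[float],
              nonneg: bool = False) -> DecayFit:
    """Fit f(x) = y0 + a·exp(−b·x); half-time = ln(2)/b.

    Requires at least 4 timepoints.  When the decay amplitude or rate is
    degenerate at the optimum (a ≈ 0 or b ≤ 0) the half-time is flagged
    undefined.  ``nonneg`` constrains y0 >= 0 and a >= 0 — appropriate for
    normalized band/spot intensities, where it stabilizes the y0-b trade-off
    of short time-courses.
    """
    t = np.asarray(time, float)
    y = np.asarray(signal, float)
    if t.size < 4:
        raise ValueError("need at least 4 timepoints")
    span = float(y[0] - y[-1])
    scale = float(np.ptp(t)) or 1.0
    if nonneg:
        p0 = [max(float(y[-1]), 1e-6), max(span, 1e-6), 1.0 / scale]
        lower = [0.0, 0.0, 1e-12]
    else:
        p0 = [float(y[-1]), span if span != 0 else max(abs(y).max(), 1e-6),
              1.0 / scale]
        lower = [-np.inf, -np.inf, 1e-12]
    try:
        popt, _ = curve_fit(
            lambda x, y0, a, b: y0 + a * np.exp(-b * x),
            t, y, p0=p0,
            bounds=(lower, [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError:
        return DecayFit(np.nan, np.nan, np.nan, np.nan, np.nan, valid=False)
    y0, a, b = (float(v) for v in popt)
    pred = y0 + a * np.exp(-b * t)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    ss_res = float(np.sum((y - pred) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res < 1e-20 else np.nan)
    amp_scale = max(abs(y).max(), 1e-12)
    degenerate = b <= 1e-10 or abs(a) < 1e-6 * amp_scale
    half = float(np.log(2) / b) if not degenerate else np.nan
    return DecayFit(y0=y0, a=a, b=b, half_time=half, r_squared=r2,
                    valid=not degenerate)


def bootstrap_ci(
    sample: DwellSample,
    model: Literal["single", "two"],
    n_boot: int = 200,
    seed: int = 0,
    level: float = 0.95,
) -> dict[str, tuple[float, float]]:
    """Case-resampling bootstrap percentile intervals for the fitted parameters."""
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    rng = np.random.default_rng(seed)
    point = fit_survival(sample, model)
    names = ["tau"] if model == "single" else ["tau1", "tau2", "alpha"]
    draws = {k: [] for k in names}
    for _ in range(n_boot):
        idx = rng.integers(0, sample.n, sample.n)
        boot = DwellSample(sample.durations[idx], t_min=sample.t_min, dt=sample.dt)
        fit = fit_survival(boot, model)
        for k in names:
            draws[k].append(getattr(fit, k))
    lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
    out = {}
    for k in names:
        arr = np.asarray(draws[k], float)
        lo, hi = np.quantile(arr, [lo_q, hi_q])
        est = getattr(point, k)
        # percentile interval widened to contain the point estimate
        out[k] = (min(float(lo), est), max(float(hi), est))
    return out
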