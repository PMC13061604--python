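"""Synthetic-data generators with exact ground truth.

Everything the downstream analysis consumes can be produced here with a
known generative model: two-channel single-particle movies (as spot/track
tables, optionally rendered frames), truncated and frame-discretized dwell
time samples, exponential chase time-courses, and per-codon selective
ribosome-profiling count tables.  A single integer seed drives every source
of randomness, so identical configs give bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DwellModel",
    "SimConfig",
    "GroundTruthLog",
    "simulate_movie",
    "simulate_dwell_sample",
    "simulate_chase",
    "simulate_ribo_counts",
    "render_frames",
]


@dataclass(frozen=True)
class DwellModel:
    """Bound-state lifetime model: single exponential or a two-component mixture.

    ``alpha`` is the fraction of component 1 (the shorter lifetime).  With
    ``tau2 is None`` (or ``alpha == 1``) the model degenerates to a single
    exponential with mean ``tau1`` seconds.
    """

    tau1: float
    tau2: float | None = None
    alpha: float = 1.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.tau1) or self.tau1 <= 0:
            raise ValueError("tau1 must be positive and finite")
        if self.tau2 is not None:
            if not np.isfinite(self.tau2) or self.tau2 <= 0:
                raise ValueError("tau2 must be positive and finite")
            if not self.tau1 < self.tau2:
                raise ValueError("require tau1 < tau2 for a mixture")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")

    @property
    def is_mixture(self) -> bool:
        return self.tau2 is not None and self.alpha < 1.0

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` continuous dwell times (seconds) from the model density."""
        if not self.is_mixture:
            return rng.exponential(self.tau1, size=n)
        comp1 = rng.random(n) < self.alpha
        out = np.where(
            comp1,
            rng.exponential(self.tau1, size=n),
            rng.exponential(self.tau2, size=n),
        )
        return out

    def mean(self) -> float:
        if not self.is_mixture:
            return self.tau1
        return self.alpha * self.tau1 + (1.0 - self.alpha) * self.tau2


@dataclass
class SimConfig:
    """Parameters of the two-channel particle-movie generator.

    Defaults emulate the imaging regime of the live-cell assays: 50-ms
    frames, 500-frame movies, immobile (ribosome/polysome-tethered) clients
    and freely diffusing chaperones that bind within a capture radius.
    """

    frame_interval: float = 0.05          # s
    n_frames: int = 500
    field_size: float = 10.0              # µm (square field)
    n_chaperones: int = 10
    n_clients: int = 10
    d_free: float = 1.0                   # µm²/s, unbound chaperone
    d_client: float = 0.0                 # µm²/s, client (≈0 when tethered)
    capture_radius: float = 0.3           # µm
    k_on: float = 5.0                     # s⁻¹ while inside capture radius
    dwell_model: DwellModel = field(default_factory=lambda: DwellModel(1.0))
    loc_sigma: float = 0.02               # µm localization noise s.d.
    jitter_bound: float = 0.05            # µm bound-chaperone offset s.d.
    p_survive_frame: float = 0.995        # photobleaching + defocalization
    refractory_frames: int = 0            # frames after release before rebinding
    seed: int = 0

    def validate(self) -> None:
        scalars = {
            "frame_interval": self.frame_interval,
            "field_size": self.field_size,
            "d_free": self.d_free,
            "d_client": self.d_client,
            "capture_radius": self.capture_radius,
            "k_on": self.k_on,
            "loc_sigma": self.loc_sigma,
            "jitter_bound": self.jitter_bound,
            "p_survive_frame": self.p_survive_frame,
        }
        for name, value in scalars.items():
            if not np.isfinite(value):
                raise ValueError(f"{name} must be finite, got {value!r}")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.n_frames < 1 or self.n_chaperones < 0 or self.n_clients < 0:
            raise ValueError("counts must be non-negative (n_frames >= 1)")
        if min(self.d_free, self.d_client, self.k_on, self.loc_sigma,
               self.jitter_bound) < 0:
            raise ValueError("rates, diffusion coefficients and sigmas must be >= 0")
        if self.capture_radius <= 0 or self.field_size <= 0:
            raise ValueError("capture_radius and field_size must be > 0")
        if not 0 < self.p_survive_frame <= 1:
            raise ValueError("p_survive_frame must be in (0, 1]")
        if self.refractory_frames < 0:
            raise ValueError("refractory_frames must be >= 0")


@dataclass
class GroundTruthLog:
    """Exact record of what the simulator did.

    ``events`` has one row per binding event (chaperone_id, client_id,
    bind_frame, release_frame, dwell_s with dwell_s the continuous draw);
    ``states`` has one row per particle per frame with the true position,
    visibility and bound-partner id (-1 when unbound).
    """

    events: pd.DataFrame
    states: pd.DataFrame


def _reflect(pos: np.ndarray, size: float) -> np.ndarray:
    """Reflecting boundary on [0, size] per axis."""
    pos = np.mod(pos, 2.0 * size)
    return np.where(pos > size, 2.0 * size - pos, pos)


def simulate_movie(config: SimConfig):
    """Simulate a dual-colour movie; return (track tables, ground truth).

    Returns
    -------
    tracks : pandas.DataFrame
        Columns ``channel`` ('chaperone'/'client'), ``track_id``, ``frame``,
        ``x_um``, ``y_um``.  One track per particle; a track ends permanently
        at the first frame the spot fails the per-frame survival draw.
    truth : GroundTruthLog
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    dt = config.frame_interval
    size = config.field_size
    n_ch, n_cl = config.n_chaperones, config.n_clients

    chap_pos = rng.uniform(0, size, size=(n_ch, 2))
    cli_pos = rng.uniform(0, size, size=(n_cl, 2))
    chap_visible = np.ones(n_ch, bool)
    cli_visible = np.ones(n_cl, bool)
    # bound_to[i] = client index or -1; release_frame[i] = last bound frame
    bound_to = np.full(n_ch, -1, int)
    release_frame = np.full(n_ch, -1, int)
    ready_frame = np.zeros(n_ch, int)     # first frame a chaperone may (re)bind
    client_occupied = np.zeros(n_cl, bool)

    p_bind = 1.0 - math.exp(-config.k_on * dt)
    sd_free = math.sqrt(2.0 * config.d_free * dt)
    sd_cli = math.sqrt(2.0 * config.d_client * dt)

    rows: list[tuple] = []
    state_rows: list[tuple] = []
    events: list[tuple] = []

    for frame in range(config.n_frames):
        if frame > 0:
            # releases scheduled after the previous frame take effect first,
            # so a just-released chaperone diffuses away this very frame
            due = (bound_to >= 0) & (release_frame < frame)
            for i in np.flatnonzero(due):
                client_occupied[bound_to[i]] = False
                chap_pos[i] = cli_pos[bound_to[i]]
                bound_to[i] = -1
                ready_frame[i] = frame + config.refractory_frames
            if sd_cli > 0:
                cli_pos = _reflect(cli_pos + rng.normal(0, sd_cli, cli_pos.shape), size)
            free = bound_to < 0
            if sd_free > 0 and free.any():
                step = rng.normal(0, sd_free, (int(free.sum()), 2))
                chap_pos[free] = _reflect(chap_pos[free] + step, size)

        # binding attempts: free, non-refractory chaperone near an open client
        free_idx = np.flatnonzero((bound_to < 0) & chap_visible
                                  & (ready_frame <= frame))
        open_idx = np.flatnonzero(~client_occupied & cli_visible)
        if free_idx.size and open_idx.size and config.k_on > 0:
            d = np.linalg.norm(
                chap_pos[free_idx, None, :] - cli_pos[None, open_idx, :], axis=2
            )
            for a, i in enumerate(free_idx):
                near = np.flatnonzero(d[a] < config.capture_radius)
                if near.size == 0:
                    continue
                j = open_idx[near[np.argmin(d[a, near])]]
                if client_occupied[j]:
                    continue
                if rng.random() < p_bind:
                    dwell = float(config.dwell_model.sample(1, rng)[0])
                    n_bound = max(1, math.ceil(dwell / dt))
                    bound_to[i] = j
                    release_frame[i] = frame + n_bound - 1
                    client_occupied[j] = True
                    events.append((int(i), int(j), frame, frame + n_bound - 1, dwell))

        # bound chaperones ride their client with jitter
        bound = np.flatnonzero(bound_to >= 0)
        if bound.size:
            jit = (rng.normal(0, config.jitter_bound, (bound.size, 2))
                   if config.jitter_bound > 0 else 0.0)
            chap_pos[bound] = cli_pos[bound_to[bound]] + jit

        # permanent disappearance (photobleaching/defocalization)
        if config.p_survive_frame < 1.0 and frame > 0:
            chap_visible &= rng.random(n_ch) < config.p_survive_frame
            cli_visible &= rng.random(n_cl) < config.p_survive_frame

        for i in range(n_ch):
            state_rows.append(("chaperone", i, frame, chap_pos[i, 0], chap_pos[i, 1],
                               bool(chap_visible[i]), int(bound_to[i])))
            if chap_visible[i]:
                noise = rng.normal(0, config.loc_sigma, 2) if config.loc_sigma > 0 else (0.0, 0.0)
                rows.append(("chaperone", i, frame,
                             chap_pos[i, 0] + noise[0], chap_pos[i, 1] + noise[1]))
        for j in range(n_cl):
            state_rows.append(("client", j, frame, cli_pos[j, 0], cli_pos[j, 1],
                               bool(cli_visible[j]), -1))
            if cli_visible[j]:
                noise = rng.normal(0, config.loc_sigma, 2) if config.loc_sigma > 0 else (0.0, 0.0)
                rows.append(("client", j, frame,
                             cli_pos[j, 0] + noise[0], cli_pos[j, 1] + noise[1]))

    tracks = pd.DataFrame(rows, columns=["channel", "track_id", "frame", "x_um", "y_um"])
    ev = pd.DataFrame(
        events,
        columns=["chaperone_id", "client_id", "bind_frame", "release_frame", "dwell_s"],
    )
    # clip events at movie end (release beyond the last frame is censored there)
    if len(ev):
        ev["release_frame"] = ev["release_frame"].clip(upper=config.n_frames - 1)
    states = pd.DataFrame(
        state_rows,
        columns=["channel", "particle_id", "frame", "x_um", "y_um", "visible", "bound_to"],
    )
    return tracks, GroundTruthLog(events=ev, states=states)


def simulate_dwell_sample(
    model: DwellModel,
    n: int,
    t_min: float = 0.5,
    dt: float = 0.05,
    seed: int = 0,
) -> np.ndarray:
    """Draw observed dwell durations: model draw + ``t_min`` offset, ceiled to the ``dt`` grid.

    Mirrors how lifetimes reach the fitting stage: sub-threshold contacts are
    excluded (every output is >= ``t_min``) and durations are counted in whole
    frames (an event covering part of a frame counts that frame), which adds
    roughly ``dt/2`` of upward bias relative to the continuous draw.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if t_min < 0 or dt <= 0:
        raise ValueError("require t_min >= 0 and dt > 0")
    rng = np.random.default_rng(seed)
    raw = model.sample(n, rng)
    frames = np.ceil(raw / dt).astype(int)
    frames = np.maximum(frames, 1)
    return t_min + frames * dt


def simulate_chase(
    y0: float,
    a: float,
    b: float,
    timepoints: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Exponential-decay time-course y(t) = y0 + a·e^(−b·t) + N(0, noise_sd)."""
    if b <= 0:
        raise ValueError("decay rate b must be > 0")
    t = np.asarray(timepoints, float)
    rng = np.random.default_rng(seed)
    y = y0 + a * np.exp(-b * t)
    if noise_sd > 0:
        y = y + rng.normal(0, noise_sd, t.shape)
    return pd.DataFrame({"time": t, "signal": y})


def simulate_ribo_counts(
    gene_length: int,
    input_depth: float,
    enrichment_windows: Sequence[tuple[int, int, float]] = (),
    dispersion: float = 0.0,
    seed: int = 0,
    gene_id: str = "gene",
) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-codon (input, IP) counts with optional enrichment windows.

    Input counts are Poisson around ``input_depth`` per codon (negative
    binomial when ``dispersion > 0``); IP counts have the same expectation
    scaled by ``fold`` inside each ``(start, end, fold)`` window (codons are
    1-based, ends inclusive).  Returns the count table and the boolean
    truth mask of in-window codons.
    """
    if gene_length < 1:
        raise ValueError("gene_length must be >= 1")
    for start, end, fold in enrichment_windows:
        if not (1 <= start <= end <= gene_length):
            raise ValueError("windows must lie within [1, gene_length]")
        if fold < 1:
            raise ValueError("fold must be >= 1")
    rng = np.random.default_rng(seed)
    mu_in = np.full(gene_length, float(input_depth))
    mu_ip = np.full(gene_length, float(input_depth))
    truth = np.zeros(gene_length, bool)
    for start, end, fold in enrichment_windows:
        mu_ip[start - 1:end] *= fold
        truth[start - 1:end] = True

    def draw(mu: np.ndarray) -> np.ndarray:
        if dispersion <= 0:
            return rng.poisson(mu)
        # NB parameterized by mean mu and dispersion phi: var = mu + phi mu^2
        r = 1.0 / dispersion
        p = r / (r + mu)
        return rng.negative_binomial(r, p)

    df = pd.DataFrame(
        {
            "gene": gene_id,
            "codon": np.arange(1, gene_length + 1),
            "input_count": draw(mu_in),
            "ip_count": draw(mu_ip),
        }
    )
    return df, truth


def render_frames(
    tracks: pd.DataFrame,
    n_frames: int,
    field_size: float,
    pixel_size: float = 0.1,
    psf_sigma_px: float = 1.2,
    photons: float = 500.0,
    background: float = 10.0,
    seed: int = 0,
    channel: str | None = None,
) -> np.ndarray:
    """Render spot tables into a 16-bit image stack (Gaussian PSF + Poisson noise).

    Off by default in the pipeline; exists to exercise the LoG detector on a
    surface with known truth.
    """
    rng = np.random.default_rng(seed)
    npx = int(round(field_size / pixel_size))
    stack = np.zeros((n_frames, npx, npx), float) + background
    sel = tracks if channel is None else tracks[tracks["channel"] == channel]
    yy, xx = np.mgrid[0:npx, 0:npx]
    for _, row in sel.iterrows():
        f = int(row["frame"])
        if not 0 <= f < n_frames:
            continue
        cx = row["x_um"] / pixel_size
        cy = row["y_um"] / pixel_size
        g = np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * psf_sigma_px**2))
        stack[f] += photons * g / (2 * np.pi * psf_sigma_px**2)
    noisy = rng.poisson(stack)
    return np.clip(noisy, 0, 65535).astype(np.uint16)
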