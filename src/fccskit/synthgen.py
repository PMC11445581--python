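"""Synthetic data with recorded ground truth for every analysis stage.

Four generators:

* :func:`simulate_photon_traces` — dual-colour photon-count traces from
  point emitters performing Brownian motion in a periodic box around a
  3-D Gaussian confocal volume, with Poisson photon statistics. A bound
  complex is simply a species that is bright in both channels.
* :func:`make_model_curves` — noiseless (or Gaussian-noise) correlation
  curves straight from the closed-form models, as a fast path for
  fitter tests.
* :func:`simulate_degradation_trace` — anaphase-aligned intensity
  trajectories: a linear photobleaching ramp multiplied by a first-order
  decay that starts at a configurable onset frame, plus Gaussian noise.
* :func:`simulate_line_profile_image` — 2-D images as sums of isotropic
  Gaussian peaks (the centrosome-chromatin-centrosome geometry) on a
  constant background.

All randomness in a generator call flows from one integer seed through a
single ``numpy.random.Generator`` stream (the Brownian kernel uses the
seeded Numba RNG), so identical inputs give bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numba
import numpy as np
from scipy.constants import Avogadro

from .fcsfit import model_g3d
from .types import CorrelationCurve, DegradationTrace, ObservationVolume, PhotonCountTrace

__all__ = [
    "SpeciesSpec",
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_photon_traces",
    "binding_species",
    "make_model_curves",
    "simulate_degradation_trace",
    "simulate_line_profile_image",
]


@dataclass(frozen=True)
class SpeciesSpec:
    """A freely diffusing fluorescent species.

    brightness values are molecular brightnesses in counts/s per molecule
    at the centre of the observation volume, per detection channel.
    """

    label: str
    diffusion_coefficient: float  # µm²/s
    concentration: float  # molar
    brightness_g: float = 0.0  # counts/s per molecule
    brightness_r: float = 0.0

    def __post_init__(self):
        vals = (self.diffusion_coefficient, self.concentration,
                self.brightness_g, self.brightness_r)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("species parameters must be finite")
        if self.diffusion_coefficient <= 0:
            raise ValueError("diffusion_coefficient must be positive")
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")
        if self.brightness_g < 0 or self.brightness_r < 0:
            raise ValueError("brightness values must be >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Geometry and discretisation of a photon-trace simulation.

    The simulation box is a periodic cuboid with half-widths
    ``box_multiplier * (w_xy, w_xy, w_z)``; a multiplier of 3 keeps
    boundary artefacts below the correlator noise while bounding the
    number of simulated molecules.
    """

    volume: ObservationVolume
    box_multiplier: float = 3.0
    bin_width: float = 1e-4  # s
    duration: float = 20.0  # s
    timestep: float = 1e-4  # s
    seed: int = 0

    def __post_init__(self):
        vals = (self.box_multiplier, self.bin_width, self.duration, self.timestep)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("simulation parameters must be finite")
        if self.box_multiplier < 3:
            raise ValueError("box_multiplier must be >= 3")
        if not self.duration > self.bin_width > 0:
            raise ValueError("require duration > bin_width > 0")
        if self.timestep > self.bin_width or self.timestep <= 0:
            raise ValueError("require 0 < timestep <= bin_width")

    @property
    def half_widths(self):
        v = self.volume
        return (self.box_multiplier * v.w_xy,
                self.box_multiplier * v.w_xy,
                self.box_multiplier * v.w_z)

    @property
    def box_volume_litres(self) -> float:
        hx, hy, hz = self.half_widths
        return 8.0 * hx * hy * hz * 1e-15

    @property
    def n_bins(self) -> int:
        return int(round(self.duration / self.bin_width))

    @property
    def substeps_per_bin(self) -> int:
        return max(1, int(round(self.bin_width / self.timestep)))


@dataclass(frozen=True)
class SyntheticTruth:
    """Full parameter record of a generating call; serialisable and
    sufficient to regenerate the dataset bit-identically."""

    generator: str
    seed: int
    params: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True,
                          default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


# Fixed number of timesteps processed per kernel call. Part of the RNG
# consumption pattern: changing it changes the simulated realisation for
# a given seed, so it is a constant, not a tuning knob.
_CHUNK_STEPS = 5000

# W(r) < exp(-16) ~ 1e-7 contributes immeasurably to any photon rate;
# skipping the exp there roughly halves the kernel cost.
_W_ARG_CUTOFF = 16.0


@numba.njit(cache=False, fastmath=True)
def _chunk_kernel(pos, disp, step_sd, bright_g, bright_r, hx, hy, hz,
                  inv_wxy2, inv_wz2, out_g, out_r):  # pragma: no cover
    n_steps = disp.shape[0]
    n = pos.shape[0]
    for t in range(n_steps):
        rate_g = 0.0
        rate_r = 0.0
        for i in range(n):
            x = pos[i, 0] + step_sd[i] * disp[t, i, 0]
            if x > hx:
                x -= 2.0 * hx
            elif x < -hx:
                x += 2.0 * hx
            y = pos[i, 1] + step_sd[i] * disp[t, i, 1]
            if y > hy:
                y -= 2.0 * hy
            elif y < -hy:
                y += 2.0 * hy
            z = pos[i, 2] + step_sd[i] * disp[t, i, 2]
            if z > hz:
                z -= 2.0 * hz
            elif z < -hz:
                z += 2.0 * hz
            pos[i, 0] = x
            pos[i, 1] = y
            pos[i, 2] = z
            q = 2.0 * ((x * x + y * y) * inv_wxy2 + z * z * inv_wz2)
            if q < _W_ARG_CUTOFF:
                w = np.exp(-q)
                rate_g += bright_g[i] * w
                rate_r += bright_r[i] * w
        out_g[t] = rate_g
        out_r[t] = rate_r


def simulate_photon_traces(
    species: Sequence[SpeciesSpec],
    config: SimulationConfig,
):
    """Simulate dual-colour photon-count traces.

    Each species contributes ``round(C * N_A * V_box)`` molecules placed
    uniformly in the periodic box. Per timestep every molecule takes an
    isotropic Gaussian step of per-axis sd sqrt(2 D dt); the photon rate
    is brightness * W(r) with W(r) = exp(-2(x^2+y^2)/w_xy^2 - 2z^2/w_z^2),
    integrated over the bin by the midpoint rule over sub-steps, and the
    bin count is Poisson-distributed around that integral.

    Returns ``(green_trace, red_trace, truth)``.
    """
    species = list(species)
    if not species:
        raise ValueError("at least one species required")
    hx, hy, hz = config.half_widths
    n_per = [int(round(s.concentration * Avogadro * config.box_volume_litres))
             for s in species]
    dt = config.timestep
    step_sd = np.concatenate([
        np.full(n, math.sqrt(2.0 * s.diffusion_coefficient * dt))
        for s, n in zip(species, n_per)
    ]) if sum(n_per) else np.empty(0)
    bright_g = np.concatenate([
        np.full(n, s.brightness_g) for s, n in zip(species, n_per)
    ]) if sum(n_per) else np.empty(0)
    bright_r = np.concatenate([
        np.full(n, s.brightness_r) for s, n in zip(species, n_per)
    ]) if sum(n_per) else np.empty(0)

    v = config.volume
    rng = np.random.default_rng(config.seed)
    n_mol = int(sum(n_per))
    pos = rng.uniform([-hx, -hy, -hz], [hx, hy, hz], size=(n_mol, 3))
    n_bins = config.n_bins
    n_sub = config.substeps_per_bin
    total_steps = n_bins * n_sub
    rate_g = np.empty(total_steps)
    rate_r = np.empty(total_steps)
    done = 0
    while done < total_steps:
        n_steps = min(_CHUNK_STEPS, total_steps - done)
        disp = rng.standard_normal((n_steps, n_mol, 3), dtype=np.float32)
        _chunk_kernel(
            pos, disp, step_sd, bright_g, bright_r, hx, hy, hz,
            1.0 / v.w_xy**2, 1.0 / v.w_z**2,
            rate_g[done : done + n_steps], rate_r[done : done + n_steps],
        )
        done += n_steps
    # midpoint-rule integral of the rate over each bin, then shot noise
    lam_g = rate_g.reshape(n_bins, n_sub).sum(axis=1) * dt
    lam_r = rate_r.reshape(n_bins, n_sub).sum(axis=1) * dt
    counts_g = rng.poisson(lam_g)
    counts_r = rng.poisson(lam_r)
    truth = SyntheticTruth(
        generator="simulate_photon_traces",
        seed=config.seed,
        params={
            "species": [dataclasses.asdict(s) for s in species],
            "n_molecules": n_per,
            "w_xy_um": v.w_xy,
            "kappa": v.kappa,
            "box_multiplier": config.box_multiplier,
            "bin_width_s": config.bin_width,
            "duration_s": config.duration,
            "timestep_s": config.timestep,
        },
    )
    green = PhotonCountTrace("green", config.bin_width, counts_g)
    red = PhotonCountTrace("red", config.bin_width, counts_r)
    return green, red, truth


def binding_species(
    total_green: float,
    total_red: float,
    kd: float,
    d_free_green: float,
    d_free_red: float,
    d_complex: float,
    brightness: float = 1e4,
):
    """Species list for a binding pair at mass-action equilibrium.

    Convenience for dual-colour simulations: partitions the totals into
    free green, free red and complex (bright in both channels) using the
    closed-form equilibrium.
    """
    from .interaction import solve_equilibrium

    eq = solve_equilibrium(total_green, total_red, kd)
    return [
        SpeciesSpec("free_green", d_free_green, eq.a_free, brightness, 0.0),
        SpeciesSpec("free_red", d_free_red, eq.b_free, 0.0, brightness),
        SpeciesSpec("complex", d_complex, eq.complex, brightness, brightness),
    ], eq


def make_model_curves(
    n_g: float,
    n_r: float,
    n_gr: float,
    tau_d_g: float,
    tau_d_r: float,
    tau_d_gr: float,
    kappa: float,
    lags: np.ndarray,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
):
    """Closed-form auto/auto/cross curves for a binding triple.

    ``n_g``/``n_r`` are free molecules per channel, ``n_gr`` the
    co-diffusing complex; total green amplitude is 1/(n_g + n_gr). With
    ``noise_sd > 0`` i.i.d. Gaussian noise of that sd is added per lag.
    Returns ``(auto_g, auto_r, cross)``.
    """
    if n_g < 0 or n_r < 0 or n_gr < 0:
        raise ValueError("molecule numbers must be >= 0")
    lags = np.asarray(lags, dtype=float)
    if lags.size == 0 or lags[0] <= 0 or (np.diff(lags) <= 0).any():
        raise ValueError("lags must be strictly increasing and positive")
    n_g_tot = n_g + n_gr
    n_r_tot = n_r + n_gr
    if n_g_tot <= 0 or n_r_tot <= 0:
        raise ValueError("each channel needs at least one molecule on average")

    def comp(n, tau_d):
        return n * model_g3d(lags, 1.0, tau_d, kappa) if n > 0 else 0.0

    auto_g = (comp(n_g, tau_d_g) + comp(n_gr, tau_d_gr)) / n_g_tot**2
    auto_r = (comp(n_r, tau_d_r) + comp(n_gr, tau_d_gr)) / n_r_tot**2
    cross = comp(n_gr, tau_d_gr) / (n_g_tot * n_r_tot)
    auto_g = np.broadcast_to(auto_g, lags.shape).astype(float).copy()
    auto_r = np.broadcast_to(auto_r, lags.shape).astype(float).copy()
    cross = np.broadcast_to(cross, lags.shape).astype(float).copy()
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        auto_g += rng.normal(0.0, noise_sd, lags.size)
        auto_r += rng.normal(0.0, noise_sd, lags.size)
        cross += rng.normal(0.0, noise_sd, lags.size)
    sd = np.full(lags.size, noise_sd) if noise_sd > 0 else None
    return (
        CorrelationCurve("auto_g", lags, auto_g, sd=sd),
        CorrelationCurve("auto_r", lags, auto_r, sd=sd),
        CorrelationCurve("cross", lags, cross, sd=sd),
    )


def degradation_closed_form(
    frames: np.ndarray,
    baseline: float,
    bleach_rate: float,
    onset_frame: int,
    decay_rate: float,
    decay_shape: str = "exponential",
    bleach_shape: str = "linear",
) -> np.ndarray:
    """Noiseless degradation model I(t) = baseline * bleach(t) * d(t).

    bleach(t) is 1 - bleach_rate*(t - first) (or exp(-bleach_rate*(t-first))
    for ``bleach_shape='exponential'``); d(t) = 1 up to and including the
    onset frame, then first-order decay exp(-decay_rate*(t - onset))
    (or a logistic sigmoid of the same rate for
    ``decay_shape='sigmoidal'``).
    """
    frames = np.asarray(frames, dtype=float)
    first = frames[0]
    if bleach_shape == "linear":
        bleach = 1.0 - bleach_rate * (frames - first)
    elif bleach_shape == "exponential":
        bleach = np.exp(-bleach_rate * (frames - first))
    else:
        raise ValueError("bleach_shape must be 'linear' or 'exponential'")
    if (bleach <= 0).any():
        raise ValueError("bleach term reaches <= 0 inside the frame range")
    dt = frames - onset_frame
    if decay_shape == "exponential":
        decay = np.where(dt <= 0, 1.0, np.exp(-decay_rate * dt))
    elif decay_shape == "sigmoidal":
        # logistic with the same small-t rate, scaled so d(onset) = 1
        decay = np.where(dt <= 0, 1.0, 2.0 / (1.0 + np.exp(2.0 * decay_rate * dt)))
    else:
        raise ValueError("decay_shape must be 'exponential' or 'sigmoidal'")
    return baseline * bleach * decay


def simulate_degradation_trace(
    baseline: float = 1.0,
    bleach_rate: float = 0.002,
    onset_frame: int = 0,
    decay_rate: float = 0.1,
    noise_sd: float = 0.02,
    frame_range=(-40, 40),
    frame_interval: float = 30.0,
    seed: int = 0,
    decay_shape: str = "exponential",
    bleach_shape: str = "linear",
    background: float = 0.0,
    compartment: str = "whole_cell",
    cell_id: str = "sim",
):
    """Single-cell degradation trajectory with known onset and rates.

    Defaults model a metaphase cell imaged every 30 s: ~20 min of
    pre-anaphase plateau bleaching at 0.2%/frame, degradation onset at
    anaphase (frame 0), first-order decay at 0.1/frame, and additive
    Gaussian noise of 2% of the plateau.
    """
    first, last = int(frame_range[0]), int(frame_range[1])
    if last <= first:
        raise ValueError("frame_range must satisfy first < last")
    if decay_rate != 0 and not (first < onset_frame <= last):
        raise ValueError("onset_frame must lie inside (first, last] "
                         "unless decay_rate is 0")
    frames = np.arange(first, last + 1)
    clean = degradation_closed_form(frames, baseline, bleach_rate, onset_frame,
                                    decay_rate, decay_shape, bleach_shape)
    rng = np.random.default_rng(seed)
    noisy = clean + background
    if noise_sd > 0:
        noisy = noisy + rng.normal(0.0, noise_sd, frames.size)
    trace = DegradationTrace(
        frames=frames,
        intensities=noisy,
        background=background,
        compartment=compartment,
        frame_interval=frame_interval,
        cell_id=cell_id,
    )
    truth = SyntheticTruth(
        generator="simulate_degradation_trace",
        seed=seed,
        params={
            "baseline": baseline,
            "bleach_rate": bleach_rate,
            "onset_frame": onset_frame,
            "decay_rate": decay_rate,
            "noise_sd": noise_sd,
            "frame_range": [first, last],
            "frame_interval_s": frame_interval,
            "decay_shape": decay_shape,
            "bleach_shape": bleach_shape,
            "background": background,
            "compartment": compartment,
        },
    )
    return trace, truth


def simulate_line_profile_image(
    peaks: Sequence[dict],
    background: float = 10.0,
    noise_sd: float = 0.0,
    image_size=(128, 128),
    seed: int = 0,
):
    """2-D images as sums of isotropic Gaussian peaks per channel.

    Each peak is ``{"center_xy": (x, y), "sd_px": s, "amplitude": a,
    "channel": name}``; coordinates are (x, y) with x the column index.
    Returns ``(images, truth)`` where images maps channel name to a 2-D
    float array of shape (ny, nx).
    """
    ny, nx = int(image_size[1]), int(image_size[0])
    channels = sorted({p.get("channel", "green") for p in peaks} | {"green"})
    for p in peaks:
        x, y = p["center_xy"]
        if not (0 <= x < nx and 0 <= y < ny):
            raise ValueError("peak centers must lie inside the image")
        if p["sd_px"] <= 0:
            raise ValueError("peak sd must be positive")
    yy, xx = np.mgrid[0:ny, 0:nx]
    images = {c: np.full((ny, nx), float(background)) for c in channels}
    for p in peaks:
        x, y = p["center_xy"]
        img = images[p.get("channel", "green")]
        img += p["amplitude"] * np.exp(
            -((xx - x) ** 2 + (yy - y) ** 2) / (2.0 * p["sd_px"] ** 2)
        )
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        for c in channels:
            images[c] = images[c] + rng.normal(0.0, noise_sd, (ny, nx))
    truth = SyntheticTruth(
        generator="simulate_line_profile_image",
        seed=seed,
        params={
            "peaks": [dict(p, center_xy=list(p["center_xy"])) for p in peaks],
            "background": background,
            "noise_sd": noise_sd,
            "image_size": [nx, ny],
        },
    )
    return images, truth
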