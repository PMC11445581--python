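"""Composite simulation-recovery experiments.

These drive the full pipeline end to end on synthetic data: simulate
photon traces at known ground truth, correlate, fit, and convert to the
physical quantities of interest. They are what the demo CLI and the
validation suite run.

Default simulation conditions emulate the live-cell operating point of
the system under study: a calibrated confocal volume of w_xy = 0.2 µm,
kappa = 5 (V_eff ~ 0.22 fL), both binding partners at ~100 nM total, the
large complex and its red-labelled subunit diffusing at 6.44 µm²/s, the
smaller free green-labelled partner at 15 µm²/s, molecular brightness
10 kHz/molecule, 20 s acquisitions binned at 100 µs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .correlator import estimate_curve_noise
from .fcsfit import NoFitSignal, fit_correlation, tau_d_from_diffusion
from .interaction import InteractionResult, interaction_from_amplitudes
from .synthgen import SimulationConfig, SpeciesSpec, binding_species, simulate_photon_traces
from .types import DiffusionFit, ObservationVolume

__all__ = ["KdExperiment", "fccs_kd_experiment", "diffusion_experiment"]

DEFAULT_VOLUME = ObservationVolume(w_xy=0.2, kappa=5.0)
D_SLOW = 6.44  # µm²/s, large ubiquitin-ligase complex
D_FAST = 15.0  # µm²/s, free ~90 kDa fluorescent fusion protein
BRIGHTNESS = 1e4  # counts/s per molecule


@dataclass(frozen=True)
class KdExperiment:
    """Per-seed results of a dual-colour K_D recovery run."""

    kd_true: float
    results: tuple  # of InteractionResult

    @property
    def kd_values(self) -> np.ndarray:
        return np.array([r.kd for r in self.results if r.valid and np.isfinite(r.kd)])

    @property
    def kd_median(self) -> float:
        return float(np.median(self.kd_values))


def fccs_kd_experiment(
    kd_true: float,
    seeds: Sequence[int],
    total_green: float = 100e-9,
    total_red: float = 100e-9,
    volume: ObservationVolume = DEFAULT_VOLUME,
    d_free_green: float = D_FAST,
    d_free_red: float = D_SLOW,
    d_complex: float = D_SLOW,
    brightness: float = BRIGHTNESS,
    duration: float = 20.0,
    bin_width: float = 1e-4,
    n_segments: int = 10,
    max_lag: Optional[float] = None,
) -> KdExperiment:
    """Recover K_D from dual-colour Brownian/Poisson simulations.

    For each seed: partition the totals into free/complex at the given
    ground-truth K_D, simulate a dual-colour trace pair, compute the two
    autocorrelations and the cross-correlation with segment-based noise
    estimates, fit single-component diffusion models, and invert the
    three fitted amplitudes to concentrations and K_D.
    """
    species, _eq = binding_species(
        total_green, total_red, kd_true,
        d_free_green, d_free_red, d_complex, brightness,
    )
    if max_lag is None:
        tau_slow = tau_d_from_diffusion(min(d_free_green, d_free_red, d_complex),
                                        volume.w_xy)
        # beyond ~box_multiplier^2 * tau_D the periodic box departs from
        # free diffusion (image correlations), so stop fitting there
        max_lag = min(9.0 * tau_slow, duration / (4.0 * n_segments))
    results = []
    for seed in seeds:
        config = SimulationConfig(
            volume=volume, duration=duration, bin_width=bin_width,
            timestep=bin_width, seed=int(seed),
        )
        green, red, _ = simulate_photon_traces(species, config)
        auto_g = estimate_curve_noise(green, green, n_segments, max_lag=max_lag)
        auto_r = estimate_curve_noise(red, red, n_segments, max_lag=max_lag)
        cross = estimate_curve_noise(green, red, n_segments, max_lag=max_lag)
        fit_g = fit_correlation(auto_g, volume)
        fit_r = fit_correlation(auto_r, volume)
        try:
            fit_x = fit_correlation(cross, volume)
            g_x0 = fit_x.amplitude if fit_x.converged else 0.0
        except NoFitSignal:
            g_x0 = 0.0
        if not (fit_g.converged and fit_r.converged):
            continue
        results.append(
            interaction_from_amplitudes(
                fit_g.amplitude, fit_r.amplitude, g_x0, volume.v_eff
            )
        )
    return KdExperiment(kd_true=kd_true, results=tuple(results))


def diffusion_experiment(
    d_true: float,
    seeds: Sequence[int],
    concentration: float = 100e-9,
    volume: ObservationVolume = DEFAULT_VOLUME,
    brightness: float = BRIGHTNESS,
    duration: float = 10.0,
    bin_width: float = 1e-4,
    n_segments: int = 10,
    max_lag: Optional[float] = None,
) -> list:
    """Single-species diffusion-coefficient recovery over seeds.

    Returns the list of converged :class:`DiffusionFit` results.
    """
    species = [SpeciesSpec("tracer", d_true, concentration, brightness, 0.0)]
    if max_lag is None:
        tau = tau_d_from_diffusion(d_true, volume.w_xy)
        max_lag = min(9.0 * tau, duration / (4.0 * n_segments))
    fits: list[DiffusionFit] = []
    for seed in seeds:
        config = SimulationConfig(
            volume=volume, duration=duration, bin_width=bin_width,
            timestep=bin_width, seed=int(seed),
        )
        green, _red, _ = simulate_photon_traces(species, config)
        curve = estimate_curve_noise(green, green, n_segments, max_lag=max_lag)
        fit = fit_correlation(curve, volume)
        if fit.converged:
            fits.append(fit)
    return fits
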