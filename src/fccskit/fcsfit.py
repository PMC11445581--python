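"""Diffusion models for confocal FCS curves and their inversion.

The observation volume is the usual 3-D Gaussian with lateral 1/e^2
radius w_xy and axial elongation kappa = w_z/w_xy. A single freely
diffusing species then gives

    G(tau) = (1/N) (1 + tau/tau_D)^-1 (1 + tau/(kappa^2 tau_D))^-1/2,

with N the mean number of molecules in V_eff = pi^{3/2} w_xy^2 w_z and
tau_D = w_xy^2 / (4 D). The module fits these models to measured curves
(weighted nonlinear least squares via lmfit) and converts fitted
parameters to concentrations, diffusion coefficients and hydrodynamic
radii. No triplet-state term is included: the proteins of interest are
slow and the fitted lag range starts above typical triplet times.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
from lmfit import Parameters, minimize
from scipy.constants import Avogadro, Boltzmann

from .types import CorrelationCurve, DiffusionFit, Environment, ObservationVolume

__all__ = [
    "NoFitSignal",
    "model_g3d",
    "model_g3d_two",
    "effective_volume",
    "concentration_from_n",
    "n_from_concentration",
    "diffusion_coefficient",
    "tau_d_from_diffusion",
    "hydrodynamic_radius",
    "diffusion_from_radius",
    "fit_correlation",
    "calibrate_volume",
]

MODEL_IDS = ("one_component_3d", "two_component_3d")


class NoFitSignal(RuntimeError):
    """The curve carries no fittable amplitude (e.g. a constant trace)."""


def _decay(tau, tau_d, kappa):
    tau = np.asarray(tau, dtype=float)
    return 1.0 / ((1.0 + tau / tau_d) * np.sqrt(1.0 + tau / (kappa**2 * tau_d)))


def model_g3d(tau, n: float, tau_d: float, kappa: float):
    """Single-component 3-D free-diffusion correlation model."""
    if n <= 0 or tau_d <= 0 or kappa <= 1:
        raise ValueError("require n > 0, tau_d > 0, kappa > 1")
    return (1.0 / n) * _decay(tau, tau_d, kappa)


def model_g3d_two(tau, n: float, f1: float, tau_d1: float, tau_d2: float,
                  kappa: float):
    """Two-component model: fraction-weighted decays with shared kappa,
    overall amplitude 1/n."""
    if not 0.0 <= f1 <= 1.0:
        raise ValueError("f1 must be in [0, 1]")
    if n <= 0 or tau_d1 <= 0 or tau_d2 <= 0 or kappa <= 1:
        raise ValueError("require n > 0, tau_d > 0, kappa > 1")
    return (1.0 / n) * (
        f1 * _decay(tau, tau_d1, kappa) + (1.0 - f1) * _decay(tau, tau_d2, kappa)
    )


def effective_volume(volume: ObservationVolume) -> float:
    """V_eff in litres: pi^{3/2} w_xy^2 w_z, 1 µm³ = 1e-15 L."""
    return volume.v_eff


def concentration_from_n(n_molecules: float, v_eff: float) -> float:
    """Molar concentration of N molecules in v_eff litres."""
    if n_molecules < 0:
        raise ValueError("n_molecules must be >= 0")
    if v_eff <= 0:
        raise ValueError("v_eff must be positive")
    return n_molecules / (Avogadro * v_eff)


def n_from_concentration(concentration: float, v_eff: float) -> float:
    """Inverse of :func:`concentration_from_n`."""
    if concentration < 0 or v_eff <= 0:
        raise ValueError("require concentration >= 0 and v_eff > 0")
    return concentration * Avogadro * v_eff


def diffusion_coefficient(tau_d: float, w_xy: float) -> float:
    """D = w_xy^2 / (4 tau_D), in µm²/s for w_xy in µm and tau_D in s."""
    if tau_d <= 0 or w_xy <= 0:
        raise ValueError("tau_d and w_xy must be positive")
    return w_xy**2 / (4.0 * tau_d)


def tau_d_from_diffusion(d_coef: float, w_xy: float) -> float:
    """Diffusion time through the volume for a given D (µm²/s)."""
    if d_coef <= 0 or w_xy <= 0:
        raise ValueError("d_coef and w_xy must be positive")
    return w_xy**2 / (4.0 * d_coef)


def hydrodynamic_radius(d_coef: float, env: Environment) -> float:
    """Stokes-Einstein radius R_h = k_B T / (6 pi eta D), in nm.

    ``d_coef`` is in µm²/s; viscosity must be supplied explicitly because
    the effective intracellular viscosity is sample-dependent.
    """
    if d_coef <= 0:
        raise ValueError("d_coef must be positive")
    d_m2 = d_coef * 1e-12
    r_m = Boltzmann * env.temperature / (6.0 * math.pi * env.viscosity * d_m2)
    return r_m * 1e9


def diffusion_from_radius(r_h_nm: float, env: Environment) -> float:
    """Inverse of :func:`hydrodynamic_radius` (returns µm²/s)."""
    if r_h_nm <= 0:
        raise ValueError("radius must be positive")
    d_m2 = Boltzmann * env.temperature / (6.0 * math.pi * env.viscosity * r_h_nm * 1e-9)
    return d_m2 * 1e12


def _initial_guesses(lags: np.ndarray, g: np.ndarray):
    g0 = g[0]
    if g0 <= 0:
        raise NoFitSignal("correlation amplitude at the first lag is <= 0")
    below = np.nonzero(g <= 0.5 * g0)[0]
    if below.size:
        tau_d0 = float(lags[below[0]])
    else:
        tau_d0 = float(math.sqrt(lags[0] * lags[-1]))
    return 1.0 / g0, tau_d0


def fit_correlation(
    curve: CorrelationCurve,
    volume: ObservationVolume,
    model_id: str = "one_component_3d",
    weights: Optional[np.ndarray] = None,
    fit_offset: bool = True,
) -> DiffusionFit:
    """Weighted least-squares fit of a diffusion model to a curve.

    kappa is held fixed at the calibrated value (refitting it against
    sample curves inflates parameter covariance). A constant baseline
    offset ``g_inf`` is fitted alongside the diffusing amplitude by
    default: measured curves do not decay exactly to zero (instrumental
    drift in experiments; the -1/N_box depletion term in closed-volume
    simulations), and absorbing that into an offset keeps N = 1/G(0) and
    tau_D unbiased. Weights default to the curve's per-lag sd when
    present; zero sd entries fall back to the smallest positive sd.
    Initial guesses are taken from the curve itself (N from the first-lag
    amplitude, tau_D from the half-amplitude lag) and the optimiser is
    restarted from perturbed initials up to three times before the fit is
    flagged as non-converged.
    """
    if model_id not in MODEL_IDS:
        raise ValueError(f"model_id must be one of {MODEL_IDS}")
    lags = curve.lags
    g = curve.g
    if len(lags) < 8:
        raise ValueError("need at least 8 lags to fit")
    sd = None
    if weights is not None:
        sd = np.asarray(weights, dtype=float)
        if (sd <= 0).any():
            raise ValueError("weights must be positive")
    elif curve.sd is not None:
        sd = curve.sd.copy()
        pos = sd[sd > 0]
        sd = np.where(sd > 0, sd, pos.min() if pos.size else 1.0)

    n0, tau_d0 = _initial_guesses(lags, g)
    kappa = volume.kappa
    two = model_id == "two_component_3d"

    def residual(params):
        if two:
            model = model_g3d_two(
                lags,
                params["n"].value,
                params["f1"].value,
                params["tau_d"].value,
                params["tau_d2"].value,
                kappa,
            )
        else:
            model = model_g3d(lags, params["n"].value, params["tau_d"].value, kappa)
        r = g - (model + params["g_inf"].value)
        return r / sd if sd is not None else r

    best = None
    perturb = [1.0, 0.5, 2.0, 5.0]
    for factor in perturb:
        params = Parameters()
        params.add("n", value=n0 * factor, min=1e-9, max=1e12)
        params.add("tau_d", value=tau_d0 * factor,
                   min=lags[0] / 1e3, max=lags[-1] * 1e3)
        if fit_offset:
            params.add("g_inf", value=0.0, min=-abs(g[0]), max=abs(g[0]))
        else:
            params.add("g_inf", value=0.0, vary=False)
        if two:
            params.add("f1", value=0.5, min=0.0, max=1.0)
            params.add("tau_d2", value=tau_d0 * factor * 10,
                       min=lags[0] / 1e3, max=lags[-1] * 1e3)
        try:
            out = minimize(residual, params, method="least_squares",
                           xtol=1e-15, ftol=1e-15, gtol=1e-15, calc_covar=False)
        except Exception:
            continue
        if best is None or out.chisqr < best.chisqr:
            best = out
        if out.success and best is out and out.chisqr <= (best.chisqr * (1 + 1e-12)):
            break

    if best is None or not best.success:
        return DiffusionFit(
            n_molecules=float("nan"), tau_d=float("nan"), d_coef=float("nan"),
            kappa_used=kappa, goodness=float("nan"), converged=False,
            model_id=model_id,
        )
    n_fit = float(best.params["n"].value)
    tau_d_fit = float(best.params["tau_d"].value)
    ndata = len(lags)
    nvary = (4 if two else 2) + (1 if fit_offset else 0)
    redchi = float(best.chisqr / max(ndata - nvary, 1))
    return DiffusionFit(
        n_molecules=n_fit,
        tau_d=tau_d_fit,
        d_coef=diffusion_coefficient(tau_d_fit, volume.w_xy),
        kappa_used=kappa,
        goodness=redchi,
        converged=True,
        model_id=model_id,
        fraction_1=float(best.params["f1"].value) if two else None,
        tau_d2=float(best.params["tau_d2"].value) if two else None,
    )


def calibrate_volume(curve: CorrelationCurve, known_d: float) -> ObservationVolume:
    """Recover the observation-volume geometry from a calibration-dye curve.

    Fits the single-component model with kappa free, then inverts
    w_xy = sqrt(4 D tau_D) using the dye's known diffusion coefficient
    (µm²/s).
    """
    if known_d <= 0:
        raise ValueError("known_d must be positive")
    lags = curve.lags
    g = curve.g
    if len(lags) < 8:
        raise ValueError("need at least 8 lags to calibrate")
    n0, tau_d0 = _initial_guesses(lags, g)
    sd = curve.sd
    if sd is not None:
        pos = sd[sd > 0]
        sd = np.where(sd > 0, sd, pos.min() if pos.size else 1.0)

    def residual(params):
        model = model_g3d(lags, params["n"].value, params["tau_d"].value,
                          params["kappa"].value)
        r = g - (model + params["g_inf"].value)
        return r / sd if sd is not None else r

    params = Parameters()
    params.add("n", value=n0, min=1e-9, max=1e12)
    params.add("tau_d", value=tau_d0, min=lags[0] / 1e3, max=lags[-1] * 1e3)
    params.add("kappa", value=5.0, min=1.0 + 1e-6, max=50.0)
    params.add("g_inf", value=0.0, min=-abs(g[0]), max=abs(g[0]))
    out = minimize(residual, params, method="least_squares", xtol=1e-15,
                   ftol=1e-15, gtol=1e-15, calc_covar=False)
    if not out.success:
        raise RuntimeError("calibration fit did not converge")
    tau_d_fit = float(out.params["tau_d"].value)
    w_xy = math.sqrt(4.0 * known_d * tau_d_fit)
    return ObservationVolume(w_xy=w_xy, kappa=float(out.params["kappa"].value))
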