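"""Dual-colour FCCS amplitude relations and mass-action equilibrium.

For a binding pair G (green) + R (red) <-> GR with all species
fluorescent, the zero-lag amplitudes of the two autocorrelations and the
cross-correlation are (s = N_A * V_eff, concentrations molar)

    G_g(0) = 1 / (s (C_gfree + C_c)),
    G_r(0) = 1 / (s (C_rfree + C_c)),
    G_x(0) = C_c / (s (C_gfree + C_c)(C_rfree + C_c)),

assuming equal molecular brightness within a channel and no spectral
cross-talk (the instrument windows for mEmerald and mScarlet are
spectrally separated). Inverting these gives absolute free and complex
concentrations and hence K_D = C_gfree * C_rfree / C_c. The
cross-correlation quotient q is the larger of the two bound fractions
G_x(0)/G_r(0) and G_x(0)/G_g(0).
"""

from __future__ import annotations

import math

from scipy.constants import Avogadro

from .types import EquilibriumState, InteractionResult

__all__ = [
    "solve_equilibrium",
    "equilibrium_amplitudes",
    "amplitudes_to_concentrations",
    "kd_from_concentrations",
    "cross_correlation_quotient",
    "interaction_from_amplitudes",
]


def solve_equilibrium(a_total: float, b_total: float, kd: float) -> EquilibriumState:
    """Closed-form 1:1 binding equilibrium.

    The complex concentration is the physical root of
    c^2 - (A + B + K) c + A B = 0, evaluated in the numerically stable
    form 2AB / ((A+B+K) + sqrt((A+B+K)^2 - 4AB)). kd = 0 is the
    infinite-affinity limit, complex = min(A, B).
    """
    if a_total < 0 or b_total < 0 or kd < 0:
        raise ValueError("concentrations and kd must be >= 0")
    if a_total == 0 or b_total == 0:
        c = 0.0
    elif kd == 0:
        c = min(a_total, b_total)
    else:
        s = a_total + b_total + kd
        disc = s * s - 4.0 * a_total * b_total
        c = 2.0 * a_total * b_total / (s + math.sqrt(max(disc, 0.0)))
    return EquilibriumState(
        a_total=a_total,
        b_total=b_total,
        kd=kd,
        a_free=a_total - c,
        b_free=b_total - c,
        complex=c,
    )


def equilibrium_amplitudes(state: EquilibriumState, v_eff: float):
    """Forward model: zero-lag amplitudes (g_g0, g_r0, g_x0) for an
    equilibrium state measured in a volume of ``v_eff`` litres."""
    if v_eff <= 0:
        raise ValueError("v_eff must be positive")
    s = Avogadro * v_eff
    n_g = s * (state.a_free + state.complex)
    n_r = s * (state.b_free + state.complex)
    if n_g <= 0 or n_r <= 0:
        raise ValueError("both channels need a non-zero total concentration")
    g_g0 = 1.0 / n_g
    g_r0 = 1.0 / n_r
    g_x0 = s * state.complex * g_g0 * g_r0
    return g_g0, g_r0, g_x0


def amplitudes_to_concentrations(g_g0: float, g_r0: float, g_x0: float,
                                 v_eff: float):
    """Invert the amplitude relations to absolute molar concentrations.

    Returns ``(c_g_free, c_r_free, c_complex)``. Negative free
    concentrations (a cross-amplitude inconsistent with the autos, which
    can happen through noise) are returned as-is so that bias remains
    visible in aggregate statistics; callers decide how to flag them.
    """
    if g_g0 <= 0 or g_r0 <= 0:
        raise ValueError("autocorrelation amplitudes must be positive")
    if g_x0 < 0:
        raise ValueError("cross amplitude must be >= 0")
    if v_eff <= 0:
        raise ValueError("v_eff must be positive")
    s = Avogadro * v_eff
    c_complex = g_x0 / (s * g_g0 * g_r0)
    c_g_free = 1.0 / (s * g_g0) - c_complex
    c_r_free = 1.0 / (s * g_r0) - c_complex
    return c_g_free, c_r_free, c_complex


def kd_from_concentrations(c_g_free: float, c_r_free: float,
                           c_complex: float) -> float:
    """K_D = free*free/complex; a zero complex concentration reports the
    non-interacting sentinel +inf."""
    if c_g_free < 0 or c_r_free < 0 or c_complex < 0:
        raise ValueError("concentrations must be >= 0")
    if c_complex == 0:
        return float("inf")
    return c_g_free * c_r_free / c_complex


def cross_correlation_quotient(g_g0: float, g_r0: float, g_x0: float):
    """Bound fractions and cross-correlation quotient q.

    bound_fraction_g = G_x(0)/G_r(0) is the fraction of green molecules
    in complex (and vice versa); q is declared as the larger of the two,
    i.e. normalised by the limiting autocorrelation.
    """
    if g_g0 <= 0 or g_r0 <= 0 or g_x0 < 0:
        raise ValueError("require positive autos and non-negative cross")
    bf_g = g_x0 / g_r0
    bf_r = g_x0 / g_g0
    return bf_g, bf_r, max(bf_g, bf_r)


def interaction_from_amplitudes(g_g0: float, g_r0: float, g_x0: float,
                                v_eff: float) -> InteractionResult:
    """Full amplitude -> concentrations -> q, K_D conversion with
    diagnostics. K_D is withheld (NaN, valid=False) when the inferred
    free concentrations are negative."""
    c_g_free, c_r_free, c_complex = amplitudes_to_concentrations(
        g_g0, g_r0, g_x0, v_eff
    )
    bf_g, bf_r, q = cross_correlation_quotient(g_g0, g_r0, g_x0)
    if c_g_free < 0 or c_r_free < 0:
        return InteractionResult(
            g_g0=g_g0, g_r0=g_r0, g_x0=g_x0,
            c_g_free=c_g_free, c_r_free=c_r_free, c_complex=c_complex,
            kd=float("nan"), bound_fraction_g=bf_g, bound_fraction_r=bf_r,
            q=q, valid=False,
            note="cross amplitude inconsistent with autocorrelations "
                 "(negative inferred free concentration)",
        )
    kd = kd_from_concentrations(c_g_free, c_r_free, c_complex)
    return InteractionResult(
        g_g0=g_g0, g_r0=g_r0, g_x0=g_x0,
        c_g_free=c_g_free, c_r_free=c_r_free, c_complex=c_complex,
        kd=kd, bound_fraction_g=bf_g, bound_fraction_r=bf_r, q=q, valid=True,
    )
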