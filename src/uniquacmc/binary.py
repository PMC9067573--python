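"""Vectorized binary UNIQUAC evaluations with analytic parameter gradients.

Training data are ln gamma observations in *binary* mixtures, so the
inference machinery never needs the general n-component engine; it needs
ln gamma of the measured species (and its infinite-dilution limit) for
many records at once, together with the derivatives with respect to the
two interaction-difference parameters

    t12 = (U_12 - U_22) / R    and    t21 = (U_12 - U_11) / R    [K].

All functions broadcast over numpy arrays. Values agree with
:func:`uniquacmc.core.ln_gamma` / :func:`~uniquacmc.core.ln_gamma_inf` to
floating rounding; the gradients are exact closed forms of the same
expressions (the Boltzmann factor tau = exp(-t/T) has d tau/dt = -tau/T,
set to zero where the exponent is clipped).
"""

from __future__ import annotations

import numpy as np

from .constants import TAU_EXPONENT_CLIP, Z_COORDINATION

__all__ = [
    "ln_gamma_binary",
    "ln_gamma_binary_grad",
    "ln_gamma_inf_binary",
    "ln_gamma_inf_binary_grad",
]


def _tau(t, T):
    """tau = exp(-t/T) with exponent clipping; returns (tau, active) where
    ``active`` is 1 inside the clip window and 0 outside (gradient mask)."""
    expo = -np.asarray(t, dtype=float) / T
    clipped = np.clip(expo, -TAU_EXPONENT_CLIP, TAU_EXPONENT_CLIP)
    return np.exp(clipped), (expo == clipped).astype(float)


def _combinatorial(r1, q1, r2, q2, x1):
    x2 = 1.0 - x1
    phi1_over_x1 = r1 / (r1 * x1 + r2 * x2)
    theta1 = q1 * x1 / (q1 * x1 + q2 * x2)
    theta2 = 1.0 - theta1
    phi1 = phi1_over_x1 * x1
    l1 = 0.5 * Z_COORDINATION * (r1 - q1) - (r1 - 1.0)
    l2 = 0.5 * Z_COORDINATION * (r2 - q2) - (r2 - 1.0)
    ln_gc = (np.log(phi1_over_x1)
             + 0.5 * Z_COORDINATION * q1 * np.log(theta1 / phi1)
             + l1 - phi1_over_x1 * (x1 * l1 + x2 * l2))
    return ln_gc, theta1, theta2


def ln_gamma_binary(r1, q1, r2, q2, t12, t21, T, x1):
    """ln gamma of species 1 at mole fraction ``x1`` in a binary mixture."""
    ln_gc, th1, th2 = _combinatorial(r1, q1, r2, q2, x1)
    tau12, _ = _tau(t12, T)
    tau21, _ = _tau(t21, T)
    s1 = th1 + th2 * tau21
    s2 = th1 * tau12 + th2
    ln_gr = q1 * (1.0 - np.log(s1) - th1 / s1 - th2 * tau12 / s2)
    return ln_gc + ln_gr


def ln_gamma_binary_grad(r1, q1, r2, q2, t12, t21, T, x1):
    """(value, d/dt12, d/dt21) of :func:`ln_gamma_binary`."""
    ln_gc, th1, th2 = _combinatorial(r1, q1, r2, q2, x1)
    tau12, a12 = _tau(t12, T)
    tau21, a21 = _tau(t21, T)
    s1 = th1 + th2 * tau21
    s2 = th1 * tau12 + th2
    value = ln_gc + q1 * (1.0 - np.log(s1) - th1 / s1 - th2 * tau12 / s2)
    # d/dtau then chain through dtau/dt = -tau/T (masked where clipped)
    d_tau21 = q1 * th2 * (th1 / s1**2 - 1.0 / s1)
    d_tau12 = q1 * th2 * (th1 * tau12 / s2**2 - 1.0 / s2)
    g12 = d_tau12 * (-tau12 / T) * a12
    g21 = d_tau21 * (-tau21 / T) * a21
    return value, g12, g21


def ln_gamma_inf_binary(r1, q1, r2, q2, t12, t21, T):
    """Infinite-dilution ln gamma of solute 1 in solvent 2."""
    tau12, _ = _tau(t12, T)
    tau21, _ = _tau(t21, T)
    l1 = 0.5 * Z_COORDINATION * (r1 - q1) - (r1 - 1.0)
    l2 = 0.5 * Z_COORDINATION * (r2 - q2) - (r2 - 1.0)
    ln_gc = (np.log(r1 / r2)
             + 0.5 * Z_COORDINATION * q1 * np.log(q1 * r2 / (q2 * r1))
             + l1 - (r1 / r2) * l2)
    return ln_gc + q1 * (1.0 - np.log(tau21) - tau12)


def ln_gamma_inf_binary_grad(r1, q1, r2, q2, t12, t21, T):
    """(value, d/dt12, d/dt21) of :func:`ln_gamma_inf_binary`."""
    tau12, a12 = _tau(t12, T)
    tau21, a21 = _tau(t21, T)
    value = ln_gamma_inf_binary(r1, q1, r2, q2, t12, t21, T)
    g12 = q1 * tau12 / T * a12       # d(-q1 tau12)/dt12
    g21 = q1 / T * a21               # d(-q1 ln tau21)/dt21
    return value, g12, g21
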