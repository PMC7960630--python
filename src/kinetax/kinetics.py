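"""Pointwise model terms: speed response, drift speeds, kinetics, flux.

All functions are vectorised over NumPy arrays and accept scalars.  The
concentration ``C``, density ``B`` and all derived quantities are
dimensionless (see :mod:`kinetax.params`).

The bacterial flux is

    J = -V(C)**2 * grad(B) + (V_k + V_chi) * B

where ``V(C)`` is the dimensionless swimming speed, ``V_k`` the chemokinetic
drift (towards lower speed, i.e. down-gradient for a positive response) and
``V_chi`` the chemotactic drift (up-gradient, with an optional correction
for temporally varying attractant fields).
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

from .params import ModelParamsND

__all__ = [
    "hill_speed",
    "speed_sensitivity",
    "chemokinetic_drift",
    "chemotactic_drift",
    "monod",
    "reaction_terms",
    "FluxComponents",
    "assemble_flux",
]


def _check_nonnegative(C, name: str = "C") -> np.ndarray:
    arr = np.asarray(C, dtype=float)
    if np.any(arr < 0):
        raise ValueError(f"{name} must be non-negative")
    return arr


def hill_speed(C, p: ModelParamsND):
    """Dimensionless swimming speed ``V(C) = 1 + eta * C^n / (C^n + omega^n)``.

    A Hill-type response: the speed rises from 1 at ``C=0`` to ``1+eta`` at
    saturation, reaching ``1 + eta/2`` at ``C = omega``.  In
    ``constant_speed`` mode the speed is ``speed_factor`` regardless of C.
    """
    arr = _check_nonnegative(C)
    if p.mode == "constant_speed":
        out = np.full_like(arr, p.speed_factor)
        return out if out.ndim else float(out)
    out = 1.0 + p.eta * _hill_fraction(arr, p.omega, p.n_hill)
    return out if out.ndim else float(out)


def _hill_fraction(arr: np.ndarray, omega: float, n: float) -> np.ndarray:
    """``C^n / (C^n + omega^n)`` computed as ``1/(1 + (omega/C)^n)``.

    The rescaled form stays finite for arbitrarily steep exponents, where
    ``C^n`` and ``omega^n`` both underflow.
    """
    with np.errstate(divide="ignore", over="ignore"):
        ratio = np.where(arr > 0, omega / np.where(arr > 0, arr, 1.0), np.inf)
        return 1.0 / (1.0 + ratio**n)


def speed_sensitivity(C, p: ModelParamsND):
    """Analytic derivative ``dV/dC = n*eta*omega^n*C^(n-1) / (C^n+omega^n)^2``.

    Zero in ``constant_speed`` mode and for ``eta = 0``; maximal near
    ``C = omega`` for the Hill family.
    """
    arr = _check_nonnegative(C)
    if p.mode == "constant_speed" or p.eta == 0.0:
        out = np.zeros_like(arr)
        return out if out.ndim else float(out)
    n, w = p.n_hill, p.omega
    if n < 1 and np.any(arr == 0):
        raise ValueError("dV/dC is singular at C=0 for n < 1")
    frac = _hill_fraction(arr, w, n)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(
            arr > 0,
            n * p.eta * frac * (1.0 - frac) / np.where(arr > 0, arr, 1.0),
            p.eta / w if n == 1 else 0.0,
        )
    return out if out.ndim else float(out)


def chemokinetic_drift(C, gradC, p: ModelParamsND):
    """Chemokinetic drift speed ``V_k = -V(C) * dV/dC * grad(C)``.

    For a positive response (``eta > 0``) the drift points towards lower
    attractant concentration (lower speed), opposing chemotaxis.
    """
    out = -hill_speed(C, p) * speed_sensitivity(C, p) * np.asarray(gradC, float)
    return out if np.ndim(out) else float(out)


def chemotactic_drift(C, gradC, dCdT, p: ModelParamsND):
    """Chemotactic drift ``V_chi = V^2 * delta0*K_chi/(C+K_chi)^2 * (gradC + zeta/V * dC/dT)``.

    The ``zeta`` term accounts for the concentration change a swimming cell
    perceives when the field itself varies in time: a decaying gradient
    (``dC/dT < 0``) weakens the drift, and the weakening is smaller at
    higher swimming speed.
    """
    arr = _check_nonnegative(C)
    V = np.asarray(hill_speed(arr, p), dtype=float)
    grad = np.asarray(gradC, dtype=float)
    pref = p.delta0 * p.K_chi / (arr + p.K_chi) ** 2
    if p.zeta > 0.0:
        with np.errstate(divide="ignore", invalid="ignore"):
            effective = grad + p.zeta / V * np.asarray(dCdT, dtype=float)
    else:
        effective = grad
    out = V**2 * pref * effective
    return out if np.ndim(out) else float(out)


def monod(C, K_S: float):
    """Monod saturation ``g(C) = C / (C + K_S)`` in [0, 1)."""
    arr = _check_nonnegative(C)
    if K_S <= 0:
        raise ValueError("K_S must be > 0")
    out = arr / (arr + K_S)
    return out if out.ndim else float(out)


def reaction_terms(B, C, p: ModelParamsND):
    """Logistic growth and Monod consumption terms.

    Returns ``(dB_growth, dC_consumption)`` with growth ``B*g(C)*(1-B)``
    (zero unless ``growth_on``) and consumption ``-H*B*g(C)`` (zero when
    ``H = 0``).  Growth and consumption are controlled independently so
    that a population can deplete an attractant it does not grow on.
    """
    Barr = _check_nonnegative(B, "B")
    g = np.asarray(monod(C, p.K_S), dtype=float)
    growth = Barr * g * (1.0 - Barr) if p.growth_on else np.zeros_like(Barr * g)
    consumption = -p.H * Barr * g
    if np.ndim(growth):
        return growth, consumption
    return float(growth), float(consumption)


class FluxComponents(NamedTuple):
    """Decomposition of the bacterial flux into its three mechanisms."""

    diffusive: np.ndarray
    chemokinetic: np.ndarray
    chemotactic: np.ndarray

    @property
    def total(self) -> np.ndarray:
        return self.diffusive + self.chemokinetic + self.chemotactic


def assemble_flux(B, gradB, C, gradC, dCdT, p: ModelParamsND) -> FluxComponents:
    """Bacterial flux ``J = -V^2 gradB + V_k B + V_chi B`` with components.

    The three contributions (speed-squared diffusion, chemokinetic drift,
    chemotactic drift) are returned individually so the two competing
    drifts can be diagnosed; ``.total`` is their sum.
    """
    V = np.asarray(hill_speed(C, p), dtype=float)
    Barr = np.asarray(B, dtype=float)
    diffusive = -(V**2) * np.asarray(gradB, dtype=float)
    vk = np.asarray(chemokinetic_drift(C, gradC, p), dtype=float) * Barr
    vchi = np.asarray(chemotactic_drift(C, gradC, dCdT, p), dtype=float) * Barr
    return FluxComponents(diffusive, vk, vchi)
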