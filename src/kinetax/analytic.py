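"""Closed-form results: drift-dominance condition and zero-flux steady state.

These serve both as standalone analysis tools and as independent oracles
for the PDE engine.
"""

from __future__ import annotations

import numpy as np

from .kinetics import hill_speed, speed_sensitivity
from .params import ModelParamsND

__all__ = [
    "NEVER",
    "dominance_condition_lhs_rhs",
    "hill_threshold",
    "steady_state_ratio",
]


class _Never:
    """Sentinel returned by :func:`hill_threshold` when the chemokinetic
    drift can never exceed the chemotactic drift (eta <= 0)."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "never"


NEVER = _Never()


def dominance_condition_lhs_rhs(C, p: ModelParamsND):
    """Both sides of the drift-dominance inequality at concentration C.

    In a stationary linear attractant profile the chemokinetic drift
    exceeds the chemotactic drift at concentration ``C`` iff ``lhs > rhs``
    with

        lhs = n*eta*omega^n*C^(n-1) / ((C^n+omega^n)^2 * V(C))
        rhs = delta0*K_chi / (C+K_chi)^2

    (the common factor ``V^2 * |gradC|`` has been divided out).
    """
    V = np.asarray(hill_speed(C, p), dtype=float)
    lhs = np.asarray(speed_sensitivity(C, p), dtype=float) / V
    rhs = p.delta0 * p.K_chi / (np.asarray(C, float) + p.K_chi) ** 2
    rhs = np.broadcast_to(np.asarray(rhs, float), lhs.shape).copy()
    if lhs.ndim:
        return lhs, rhs
    return float(lhs), float(rhs)


def hill_threshold(p: ModelParamsND):
    """Hill exponent above which chemokinesis dominates chemotaxis at C=omega.

    Evaluating the dominance condition at the concentration of steepest
    speed change, ``C = omega``, gives the closed-form threshold

        n* = 4*delta0*omega*K_chi / (omega+K_chi)^2 * (1/eta + 1/2).

    For ``eta <= 0`` the two drifts do not compete at ``C = omega`` (a
    negative response is stabilising) and the sentinel :data:`NEVER` is
    returned.
    """
    if p.eta <= 0:
        return NEVER
    return (
        4.0 * p.delta0 * p.omega * p.K_chi / (p.omega + p.K_chi) ** 2
        * (1.0 / p.eta + 0.5)
    )


def steady_state_ratio(C_profile, ref_index: int, p: ModelParamsND):
    """Zero-flux steady-state density ratio ``B/B*`` for a frozen attractant.

    With homogeneous Neumann boundaries the steady flux vanishes
    identically, which integrates to

        B/B* = (V*/V) * exp{ delta0 * [C/(C+K_chi) - C*/(C*+K_chi)] }

    where starred quantities are taken at ``C_profile[ref_index]``.  The
    ``V*/V`` factor is the chemokinetic accumulation at low speed; with a
    uniform speed the expression reduces to the purely chemotactic
    exponential.
    """
    C = np.asarray(C_profile, dtype=float)
    if not 0 <= ref_index < C.size:
        raise IndexError("ref_index outside the profile")
    V = np.asarray(hill_speed(C, p), dtype=float)
    f = C / (C + p.K_chi)
    Vref = V.flat[ref_index]
    fref = f.flat[ref_index]
    return (Vref / V) * np.exp(p.delta0 * (f - fref))
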