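"""Model parameter sets and the dimensional/dimensionless mapping.

The continuum model is solved in dimensionless form.  Time is measured in
units of the inverse maximum growth rate ``t0 = 1/k_g``, space in units of
``x0 = sqrt(t0 * D_b0)`` where ``D_b0 = v0**2 / alpha`` is the run-and-tumble
diffusivity at the base swimming speed ``v0`` and tumble rate ``alpha``, and
the bacterial density and attractant concentration are rescaled by their
characteristic values ``b0`` and ``c0``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal

__all__ = [
    "ModelParamsND",
    "DimensionalParams",
    "Scales",
    "nondimensionalize",
    "dimensionalize",
]

Mode = Literal["chemokinetic", "constant_speed"]


@dataclass(frozen=True)
class ModelParamsND:
    """Dimensionless parameters of the chemotaxis--chemokinesis model.

    Parameters
    ----------
    N : float
        Ratio of attractant to bacterial diffusivity, ``D_c / D_b0``.
    H : float
        Consumption strength ``b0 / (Y * c0)``; ``H = 0`` disables
        attractant consumption.
    K_S : float
        Monod half-saturation of growth/consumption, in units of ``c0``.
    eta : float
        Maximum relative swimming-speed increase of the chemokinetic
        response (>= -1; negative values model negative chemokinesis).
    omega : float
        Attractant concentration at which half the maximal speed increase
        is reached (> 0), in units of ``c0``.
    n_hill : float
        Hill exponent of the speed response (>= 1); large ``n`` approaches
        a step response.
    delta0 : float
        Chemotactic sensitivity ratio ``chi0 / D_b0`` (>= 0).
    zeta : float
        Temporal-correction coefficient ``v0 / (alpha * x0)`` (>= 0); scales
        the contribution of the perceived temporal attractant change to the
        chemotactic drift.
    K_chi : float
        Half-saturation of the chemotactic receptor function (> 0), in
        units of ``c0``.
    growth_on : bool
        Whether the logistic growth term is active.  Consumption of the
        attractant is governed by ``H`` alone.
    mode : {"chemokinetic", "constant_speed"}
        ``constant_speed`` fixes the dimensionless speed to ``speed_factor``
        everywhere: diffusivity ``speed_factor**2``, chemotactic prefactor
        ``delta0 * speed_factor**2``, and zero chemokinetic drift.
    speed_factor : float
        Uniform dimensionless speed ``s`` used in ``constant_speed`` mode
        (>= 0; ignored otherwise).
    """

    N: float = 0.0
    H: float = 0.0
    K_S: float = 1.0
    eta: float = 0.0
    omega: float = 0.2
    n_hill: float = 1.0
    delta0: float = 0.0
    zeta: float = 0.0
    K_chi: float = 1.0
    growth_on: bool = False
    mode: Mode = "chemokinetic"
    speed_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.omega <= 0:
            raise ValueError(f"omega must be > 0, got {self.omega}")
        if self.K_chi <= 0:
            raise ValueError(f"K_chi must be > 0, got {self.K_chi}")
        if self.K_S <= 0:
            raise ValueError(f"K_S must be > 0, got {self.K_S}")
        if self.n_hill < 1:
            raise ValueError(f"n_hill must be >= 1, got {self.n_hill}")
        if self.delta0 < 0:
            raise ValueError(f"delta0 must be >= 0, got {self.delta0}")
        if self.zeta < 0:
            raise ValueError(f"zeta must be >= 0, got {self.zeta}")
        if self.eta < -1:
            raise ValueError(f"eta must be >= -1, got {self.eta}")
        if self.N < 0 or self.H < 0:
            raise ValueError("N and H must be >= 0")
        if self.mode not in ("chemokinetic", "constant_speed"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "constant_speed" and self.speed_factor < 0:
            raise ValueError("speed_factor must be >= 0")

    def with_overrides(self, **kwargs) -> "ModelParamsND":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class Scales:
    """Characteristic scales linking dimensional and dimensionless forms."""

    t0: float  # 1 / k_g
    x0: float  # sqrt(t0 * D_b0)
    D_b0: float  # v0**2 / alpha
    b0: float
    c0: float


@dataclass(frozen=True)
class DimensionalParams:
    """Dimensional model parameters.

    Units are arbitrary but must be mutually consistent (e.g. micrometres,
    seconds and micromolar).  ``beta`` is the chemotactic response constant
    that sets ``chi = v**2 * beta / alpha``.
    """

    v0: float  # base swimming speed, length/time
    v_c: float  # maximum speed increase, length/time
    k_c: float  # chemokinetic half-saturation, concentration
    alpha: float  # tumble rate, 1/time
    beta: float  # chemotactic response constant (dimensionless)
    k_chi: float  # chemotactic half-saturation, concentration
    k_g: float  # maximum growth rate, 1/time
    Y: float  # yield, density/concentration
    k_b: float  # carrying capacity, density
    k_s: float  # Monod half-saturation, concentration
    D_c: float  # attractant diffusivity, length**2/time
    b0: float  # density scale
    c0: float  # concentration scale

    def __post_init__(self) -> None:
        for name in ("v0", "alpha", "k_g", "Y", "k_b", "k_s", "k_c",
                     "k_chi", "b0", "c0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.v_c < -self.v0:
            raise ValueError("v_c must not reduce the speed below zero")
        if self.D_c < 0 or self.beta < 0:
            raise ValueError("D_c and beta must be >= 0")

    @property
    def chi0(self) -> float:
        """Base chemotactic sensitivity ``chi0 = v0**2 * beta / alpha``."""
        return self.v0**2 * self.beta / self.alpha


def nondimensionalize(
    d: DimensionalParams, *, growth_on: bool = False
) -> tuple[ModelParamsND, Scales]:
    """Map a dimensional parameter set to the dimensionless one.

    Returns the dimensionless parameters together with the characteristic
    scales ``t0 = 1/k_g``, ``D_b0 = v0**2/alpha`` and ``x0 = sqrt(t0*D_b0)``.

    Notes
    -----
    The dimensionless logistic term ``(1 - B)`` presumes the density scale
    is the carrying capacity, so ``growth_on=True`` requires ``b0 == k_b``.
    """
    t0 = 1.0 / d.k_g
    D_b0 = d.v0**2 / d.alpha
    x0 = math.sqrt(t0 * D_b0)
    if growth_on and not math.isclose(d.b0, d.k_b, rel_tol=1e-12):
        raise ValueError(
            "growth requires the density scale b0 to equal the carrying "
            f"capacity k_b (got b0={d.b0}, k_b={d.k_b})"
        )
    p = ModelParamsND(
        N=d.D_c / D_b0,
        H=d.b0 / (d.Y * d.c0),
        K_S=d.k_s / d.c0,
        eta=d.v_c / d.v0,
        omega=d.k_c / d.c0,
        n_hill=1.0,
        delta0=d.chi0 / D_b0,  # == beta
        zeta=d.v0 / (d.alpha * x0),
        K_chi=d.k_chi / d.c0,
        growth_on=growth_on,
    )
    return p, Scales(t0=t0, x0=x0, D_b0=D_b0, b0=d.b0, c0=d.c0)


def dimensionalize(p: ModelParamsND, scales: Scales) -> DimensionalParams:
    """Invert :func:`nondimensionalize` for the given scales.

    The swimming parameters are recovered from ``zeta = v0/(alpha*x0)`` and
    ``D_b0 = v0**2/alpha``, which give ``v0 = D_b0/(zeta*x0)``; this requires
    ``zeta > 0``.
    """
    if p.zeta <= 0:
        raise ValueError("dimensionalize requires zeta > 0")
    v0 = scales.D_b0 / (p.zeta * scales.x0)
    alpha = v0**2 / scales.D_b0
    k_g = 1.0 / scales.t0
    return DimensionalParams(
        v0=v0,
        v_c=p.eta * v0,
        k_c=p.omega * scales.c0,
        alpha=alpha,
        beta=p.delta0,
        k_chi=p.K_chi * scales.c0,
        k_g=k_g,
        Y=scales.b0 / (p.H * scales.c0) if p.H > 0 else float("inf"),
        k_b=scales.b0,
        k_s=p.K_S * scales.c0,
        D_c=p.N * scales.D_b0,
        b0=scales.b0,
        c0=scales.c0,
    )
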