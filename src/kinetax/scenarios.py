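"""Benchmark scenario constructors and the TOML config round trip.

Three set-ups are provided, mirroring common experimental geometries:

* ``make_linear_gradient`` -- a fixed linear attractant profile in a 1D
  channel (microfluidic gradient chamber); no consumption or growth.
* ``make_agar_plate`` -- an initially uniform nutrient field consumed by a
  growing population inoculated at the centre of an axisymmetric domain;
  the population follows its self-generated gradient outwards as a
  travelling wave.
* ``make_transient_source`` -- a diffusing attractant pulse from a
  point-like release (lysed alga, exuding particle) with bacteria
  initially uniform; consumption active, growth off.

Scenario defaults store the benchmark parameter sets verbatim as data.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import numpy as np

from .engine import FieldState, StepControl, Trajectory, advance
from .grid import Grid
from .params import ModelParamsND

__all__ = [
    "Variant",
    "ScenarioSpec",
    "gaussian_pulse",
    "gaussian_pulse_rate",
    "make_linear_gradient",
    "make_agar_plate",
    "make_transient_source",
    "run_variant",
    "boundary_sensitivity",
]


def gaussian_pulse(R, T: float, S: float, N: float):
    """2D diffusion kernel ``C(R,T) = S/(4*pi*N*T) * exp(-R^2/(4*N*T))``.

    ``S`` is the total attractant content of the pulse:
    ``integral C * 2*pi*R dR = S`` at every time.
    """
    if T <= 0:
        raise ValueError("T must be > 0")
    if N <= 0:
        raise ValueError("N must be > 0")
    R = np.asarray(R, dtype=float)
    out = S / (4.0 * np.pi * N * T) * np.exp(-(R**2) / (4.0 * N * T))
    return out if out.ndim else float(out)


def gaussian_pulse_rate(R, T: float, S: float, N: float):
    """Analytic ``dC/dT`` of :func:`gaussian_pulse`."""
    C = np.asarray(gaussian_pulse(R, T, S, N), dtype=float)
    R = np.asarray(R, dtype=float)
    out = C * (R**2 / (4.0 * N * T**2) - 1.0 / T)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class Variant:
    """A comparison parameter set: a label plus field overrides."""

    label: str
    overrides: dict

    def apply(self, base: ModelParamsND) -> ModelParamsND:
        return base.with_overrides(**self.overrides)


_INITIAL_KEYS = {
    "c_profile", "c_max", "c_level", "pulse_S", "pulse_T0",
    "b_profile", "b_level", "b_center", "b_width", "b_norm",
}


@dataclass
class ScenarioSpec:
    """Geometry, parameters, initial conditions and outputs of one set-up.

    Initial conditions are stored as a small description (``initial``
    dict) and realised on the grid by :meth:`build_initial_state`, so a
    spec round-trips losslessly through its config file.
    """

    name: str
    grid: Grid
    params: ModelParamsND
    c_mode: str  # "frozen" | "dynamic"
    t_snapshots: list[float]
    initial: dict
    variants: list[Variant] = field(default_factory=list)
    c_analytic: bool = False  # impose the pulse kernel instead of evolving C

    def __post_init__(self) -> None:
        if self.c_mode not in ("frozen", "dynamic"):
            raise ValueError(f"unknown c_mode {self.c_mode!r}")
        ts = list(self.t_snapshots)
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError("snapshot times must be strictly increasing")
        unknown = set(self.initial) - _INITIAL_KEYS
        if unknown:
            raise ValueError(f"unknown initial-condition keys: {sorted(unknown)}")

    # ------------------------------------------------------------------ #
    @property
    def T0(self) -> float:
        return float(self.initial.get("pulse_T0", 0.0))

    def build_initial_state(self) -> FieldState:
        """Realise the initial condition description on the grid."""
        x = self.grid.cell_centers
        ini = self.initial
        cp = ini["c_profile"]
        if cp == "linear":
            c_max = float(ini.get("c_max", 1.0))
            C = c_max * (x - self.grid.x_min) / (self.grid.x_max - self.grid.x_min)
        elif cp == "uniform":
            C = np.full_like(x, float(ini.get("c_level", 1.0)))
        elif cp == "pulse":
            C = gaussian_pulse(x, self.T0, float(ini["pulse_S"]), self.params.N)
        else:
            raise ValueError(f"unknown c_profile {cp!r}")

        bp = ini["b_profile"]
        if bp == "uniform":
            B = np.full_like(x, float(ini["b_level"]))
        elif bp == "gaussian":
            center = float(ini["b_center"])
            width = float(ini["b_width"])
            level = float(ini["b_level"])
            shape = np.exp(-((x - center) ** 2) / (2.0 * width**2))
            if ini.get("b_norm", "peak") == "mean":
                # scale so the volume-weighted domain mean equals b_level
                w = self.grid.cell_volumes
                B = level * shape * (np.sum(w) / np.sum(shape * w))
            else:
                B = level * shape
        else:
            raise ValueError(f"unknown b_profile {bp!r}")
        return FieldState(self.T0, B, C)

    def variant_params(self, label: str | None = None) -> ModelParamsND:
        """Parameters of one run; ``None`` or ``"base"`` selects the base set."""
        if label is None or label == "base":
            return self.params
        for v in self.variants:
            if v.label == label:
                return v.apply(self.params)
        raise KeyError(f"unknown variant {label!r}")

    def iter_runs(self) -> Iterator[tuple[str, ModelParamsND]]:
        """Yield ``(label, params)`` for the base set and every variant."""
        yield "base", self.params
        for v in self.variants:
            yield v.label, v.apply(self.params)

    # ------------------------- config round trip ---------------------- #
    def to_toml(self, path: str | Path) -> None:
        """Write the scenario as a flat sectioned key-value config file."""
        lines = ["[scenario]"]
        lines.append(f'name = "{self.name}"')
        lines.append(f'c_mode = "{self.c_mode}"')
        lines.append(f"c_analytic = {str(self.c_analytic).lower()}")
        lines.append("")
        lines.append("[grid]")
        g = self.grid
        lines.append(f'geometry = "{g.geometry}"')
        lines.append(f"x_min = {g.x_min!r}")
        lines.append(f"x_max = {g.x_max!r}")
        lines.append(f"n_cells = {g.n_cells}")
        lines.append("")
        lines.append("[params]")
        for key, val in _params_to_dict(self.params).items():
            lines.append(f"{key} = {_toml_value(val)}")
        lines.append("")
        lines.append("[initial]")
        for key, val in self.initial.items():
            lines.append(f"{key} = {_toml_value(val)}")
        lines.append("")
        lines.append("[output]")
        lines.append(f"t_snapshots = {_toml_value(list(self.t_snapshots))}")
        for v in self.variants:
            lines.append("")
            lines.append(f"[variants.{v.label}]")
            for key, val in v.overrides.items():
                lines.append(f"{key} = {_toml_value(val)}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_toml(cls, path: str | Path) -> "ScenarioSpec":
        """Load a scenario config, rejecting unknown sections and keys."""
        with open(path, "rb") as fh:
            doc = tomllib.load(fh)
        known_sections = {"scenario", "grid", "params", "initial", "output", "variants"}
        unknown = set(doc) - known_sections
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        missing = {"grid", "params", "initial"} - set(doc)
        if missing:
            raise ValueError(f"missing config sections: {sorted(missing)}")
        sc = doc.get("scenario", {})
        _reject_unknown(sc, {"name", "c_mode", "c_analytic"}, "scenario")
        gsec = doc["grid"]
        _reject_unknown(gsec, {"geometry", "x_min", "x_max", "n_cells"}, "grid")
        grid = Grid(gsec["geometry"], float(gsec["x_min"]), float(gsec["x_max"]),
                    int(gsec["n_cells"]))
        psec = doc["params"]
        param_fields = set(_params_to_dict(ModelParamsND()))
        _reject_unknown(psec, param_fields, "params")
        params = ModelParamsND(**psec)
        isec = doc["initial"]
        _reject_unknown(isec, _INITIAL_KEYS, "initial")
        osec = doc.get("output", {})
        _reject_unknown(osec, {"t_snapshots"}, "output")
        variants = []
        for label, ov in doc.get("variants", {}).items():
            _reject_unknown(ov, param_fields, f"variants.{label}")
            variants.append(Variant(label, dict(ov)))
        return cls(
            name=sc.get("name", Path(path).stem),
            grid=grid,
            params=params,
            c_mode=sc.get("c_mode", "dynamic"),
            t_snapshots=[float(t) for t in osec.get("t_snapshots", [])],
            initial=dict(isec),
            variants=variants,
            c_analytic=bool(sc.get("c_analytic", False)),
        )


def _params_to_dict(p: ModelParamsND) -> dict:
    return {
        "N": p.N, "H": p.H, "K_S": p.K_S, "eta": p.eta, "omega": p.omega,
        "n_hill": p.n_hill, "delta0": p.delta0, "zeta": p.zeta,
        "K_chi": p.K_chi, "growth_on": p.growth_on, "mode": p.mode,
        "speed_factor": p.speed_factor,
    }


def _toml_value(val) -> str:
    if isinstance(val, bool):
        return str(val).lower()
    if isinstance(val, str):
        return f'"{val}"'
    if isinstance(val, (list, tuple)):
        return "[" + ", ".join(_toml_value(v) for v in val) + "]"
    if isinstance(val, int):
        return str(val)
    return repr(float(val))


def _reject_unknown(section: dict, allowed: set, name: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ValueError(f"unknown keys in [{name}]: {sorted(unknown)}")


# ---------------------------------------------------------------------- #
#  Benchmark constructors
# ---------------------------------------------------------------------- #

def make_linear_gradient(
    p_overrides: dict | None = None,
    *,
    n_cells: int = 400,
    domain: float = 10.0,
    variants: list[Variant] | None = None,
) -> ScenarioSpec:
    """Fixed linear attractant profile in a 1D channel.

    The attractant rises linearly from 0 at the left boundary to
    ``c_max = 1`` at the right and is frozen in time (no diffusion, no
    consumption).  Bacteria start as a narrow bump near the low-attractant
    side.  Default variants: the pure-chemotaxis control (``eta = 0``) and
    a sweep of the Hill exponent, n = 1, 5, 10, 40.
    """
    params = ModelParamsND(
        N=0.0, H=0.0, K_S=1.0, K_chi=0.53, delta0=50.0,
        eta=2.0, omega=0.2, n_hill=5.0, zeta=0.0, growth_on=False,
    )
    if p_overrides:
        params = params.with_overrides(**p_overrides)
    if variants is None:
        variants = [
            Variant("pure_chemotaxis", {"eta": 0.0}),
            Variant("n_1", {"n_hill": 1.0}),
            Variant("n_5", {"n_hill": 5.0}),
            Variant("n_10", {"n_hill": 10.0}),
            Variant("n_40", {"n_hill": 40.0}),
        ]
    return ScenarioSpec(
        name="linear_gradient",
        grid=Grid("cartesian1d", 0.0, domain, n_cells),
        params=params,
        c_mode="frozen",
        t_snapshots=[0.5, 1.0, 9.0, 17.0],
        initial={
            "c_profile": "linear", "c_max": 1.0,
            # localized inoculum near the low-attractant side; width 2% of
            # the domain, scaled so the domain-mean density is 0.2 (shape
            # conclusions are qualitative)
            "b_profile": "gaussian", "b_center": 0.05 * domain,
            "b_width": 0.02 * domain, "b_level": 0.2, "b_norm": "mean",
        },
        variants=variants,
    )


def make_agar_plate(
    p_overrides: dict | None = None,
    *,
    n_cells: int = 1800,
    domain: float = 120.0,
    variants: list[Variant] | None = None,
) -> ScenarioSpec:
    """Self-generated gradient on an axisymmetric plate.

    The attractant is initially uniform (C = 1) and is consumed by a
    population inoculated at the origin; growth is on.  The attractant
    profile travels with the bacterial wave, so the temporal chemotaxis
    correction is switched off (zeta = 0).  Variants: purely chemotactic
    populations at uniform speed 1 and ``1 + eta``.
    """
    params = ModelParamsND(
        N=0.5, H=3.5, K_S=1.0, K_chi=0.53, delta0=105.0,
        eta=0.5, omega=0.5, n_hill=5.0, zeta=0.0, growth_on=True,
    )
    if p_overrides:
        params = params.with_overrides(**p_overrides)
    if variants is None:
        variants = [
            Variant("const_speed_base", {"mode": "constant_speed",
                                         "speed_factor": 1.0}),
            Variant("const_speed_high", {"mode": "constant_speed",
                                         "speed_factor": 1.0 + params.eta}),
        ]
    snaps = sorted(set(np.round(np.arange(0.5, 16.5, 0.5), 6)) | {1.0, 8.8, 16.4})
    return ScenarioSpec(
        name="agar_plate",
        grid=Grid("axisymmetric", 0.0, domain, n_cells),
        params=params,
        c_mode="dynamic",
        t_snapshots=[float(t) for t in snaps],
        initial={
            "c_profile": "uniform", "c_level": 1.0,
            "b_profile": "gaussian", "b_center": 0.0,
            "b_width": 0.02 * domain, "b_level": 1.0,
        },
        variants=variants,
    )


def make_transient_source(
    p_overrides: dict | None = None,
    *,
    n_cells: int = 600,
    domain: float = 10.0,
    variants: list[Variant] | None = None,
    c_analytic: bool = False,
    t_end: float = 1.0,
) -> ScenarioSpec:
    """Diffusing attractant pulse from a point-like transient source.

    The attractant starts as the 2D heat kernel at ``T0 = 0.01`` with
    content ``S = 0.5`` and keeps diffusing (and, by default, being
    consumed, ``H = 3.5``) while the initially uniform population
    (B = 0.2) accumulates at the source.  Growth is off.  The temporal
    chemotaxis correction is active, ``zeta = 8.164e-3``.  Variants cover
    the four combinations {chemokinetic, pure chemotaxis} x {zeta as set,
    zeta = 0}.

    Set ``c_analytic=True`` to impose the analytic kernel instead of
    evolving the attractant PDE.
    """
    params = ModelParamsND(
        N=0.5, H=3.5, K_S=1.0, K_chi=0.53, delta0=50.0,
        eta=2.0, omega=0.2, n_hill=1.0, zeta=8.164e-3, growth_on=False,
    )
    if p_overrides:
        params = params.with_overrides(**p_overrides)
    if variants is None:
        variants = [
            Variant("ck_zeta", {}),
            Variant("ck_nozeta", {"zeta": 0.0}),
            Variant("chemo_zeta", {"eta": 0.0}),
            Variant("chemo_nozeta", {"eta": 0.0, "zeta": 0.0}),
        ]
    snaps = sorted(set(np.round(np.arange(0.02, t_end + 1e-9, 0.02), 6))
                   | {0.05, 0.64} | {t_end})
    snaps = [float(t) for t in snaps if t <= t_end + 1e-12]
    return ScenarioSpec(
        name="transient_source",
        grid=Grid("axisymmetric", 0.0, domain, n_cells),
        params=params,
        c_mode="dynamic",
        t_snapshots=snaps,
        initial={
            "c_profile": "pulse", "pulse_S": 0.5, "pulse_T0": 0.01,
            "b_profile": "uniform", "b_level": 0.2,
        },
        variants=variants,
        c_analytic=c_analytic,
    )


# ---------------------------------------------------------------------- #
#  Running
# ---------------------------------------------------------------------- #

def run_variant(
    spec: ScenarioSpec,
    label: str | None = None,
    *,
    control: StepControl = StepControl(),
    n_cells: int | None = None,
) -> Trajectory:
    """Run one variant of a scenario and return its snapshot trajectory."""
    grid = spec.grid if n_cells is None else spec.grid.with_resolution(n_cells)
    spec_run = replace(spec, grid=grid) if n_cells is not None else spec
    params = spec.variant_params(label)
    state = replace(spec_run, params=params).build_initial_state()
    c_prescribed = None
    if spec.c_analytic:
        if spec.initial.get("c_profile") != "pulse":
            raise ValueError("c_analytic requires a pulse attractant profile")
        S = float(spec.initial["pulse_S"])
        N = params.N

        def c_prescribed(T, r, S=S, N=N):
            return gaussian_pulse(r, T, S, N), gaussian_pulse_rate(r, T, S, N)

    T_end = spec.t_snapshots[-1]
    return advance(
        state, grid, params, T_end,
        snapshot_times=spec.t_snapshots[:-1],
        c_mode=spec.c_mode,
        control=control,
        c_prescribed=c_prescribed,
    )


def boundary_sensitivity(
    spec: ScenarioSpec,
    label: str | None = None,
    *,
    T: float | None = None,
    control: StepControl = StepControl(),
) -> dict:
    """Quantify finite-domain effects by doubling the domain at fixed dx.

    Runs the chosen variant to time ``T`` (default: the last snapshot) on
    the configured domain and on a domain twice as large (same spacing),
    and reports the relative change of the peak density and of the
    population contained within the original domain.
    """
    from .observables import peak_density

    T = spec.t_snapshots[-1] if T is None else T
    results = {}
    for tag, factor in (("base", 1), ("doubled", 2)):
        grid = Grid(spec.grid.geometry, spec.grid.x_min,
                    spec.grid.x_min + factor * (spec.grid.x_max - spec.grid.x_min),
                    factor * spec.grid.n_cells)
        sub = replace(spec, grid=grid, t_snapshots=[T])
        traj = run_variant(sub, label, control=control)
        state = traj.final
        inside = grid.cell_centers <= spec.grid.x_max
        results[tag] = {
            "peak": peak_density(state)[0],
            "total": float(np.sum(state.B[inside] * grid.cell_volumes[inside])),
        }
    out = {}
    for key in ("peak", "total"):
        a, b = results["base"][key], results["doubled"][key]
        out[key + "_rel_change"] = abs(b - a) / max(abs(a), 1e-300)
    return out
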