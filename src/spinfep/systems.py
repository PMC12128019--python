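"""Two-electronic-state energy backends and the λ-mixed alchemical Hamiltonian.

A :class:`TwoStateSystem` bundles a particle layout (masses, frozen mask)
with a backend able to return the potential energy and gradient of the same
nuclear configuration on *two* electronic surfaces — here labelled
``singlet`` and ``triplet``.  The alchemical Hamiltonian interpolates
between them linearly,

    H(λ) = (1 − λ) H_S + λ H_T,

so that λ = 0 is the pure singlet state, λ = 1 the pure triplet state, and
intermediate λ values define the unphysical mixed states used as FEP
windows.  Only the potential energy is mixed: both spin states share the
same nuclei and masses, so the kinetic term is state-independent and
cancels identically in every energy difference the estimators consume.

Analytic backends (harmonic and quartic pairs, and a harmonic pair dressed
with a common-mode environment term) stand in for quantum-chemistry
surfaces and give closed-form or quadrature free energies against which
the FEP machinery is validated.  A real QM/MM engine would plug in through
the ``external_stub`` contract: one call returning (E, ∇E) for both spin
states at a given geometry.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Union

import numpy as np
from numpy.typing import NDArray

from .constants import kt
from .errors import AccuracyError, InputError, UnsupportedBackendError

if sys.version_info >= (3, 11):
    import tomllib
else:  # pragma: no cover
    import tomli as tomllib

State = Literal["singlet", "triplet"]

SYSTEM_FORMAT = "spinfep-system-v1"


def _as_float_array(values, name: str, size: int | None = None) -> NDArray[np.float64]:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise InputError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if size is not None and arr.size != size:
        raise InputError(f"{name} must have length {size}, got {arr.size}")
    return arr


@dataclass(frozen=True)
class HarmonicPairParams:
    """Per-coordinate harmonic surfaces for both spin states.

    E_state(x) = E0_state + Σ_i ½ k_state,i (x_i − x0_state,i)²
    """

    k_s: NDArray[np.float64]
    k_t: NDArray[np.float64]
    x0_s: NDArray[np.float64]
    x0_t: NDArray[np.float64]
    e0_s: float = 0.0
    e0_t: float = 0.0

    def __post_init__(self) -> None:
        n = _as_float_array(self.k_s, "k_s").size
        for name in ("k_s", "k_t", "x0_s", "x0_t"):
            arr = _as_float_array(getattr(self, name), name, n)
            object.__setattr__(self, name, arr)
        if np.any(self.k_s <= 0) or np.any(self.k_t <= 0):
            raise InputError("all force constants must be positive")

    @property
    def n_coords(self) -> int:
        return int(self.k_s.size)


@dataclass(frozen=True)
class QuarticPairParams:
    """Harmonic-plus-quartic surfaces: E = E0 + Σ ½k(x−x0)² + c4 (x−x0)⁴."""

    k_s: NDArray[np.float64]
    k_t: NDArray[np.float64]
    c4_s: NDArray[np.float64]
    c4_t: NDArray[np.float64]
    x0_s: NDArray[np.float64]
    x0_t: NDArray[np.float64]
    e0_s: float = 0.0
    e0_t: float = 0.0

    def __post_init__(self) -> None:
        n = _as_float_array(self.k_s, "k_s").size
        for name in ("k_s", "k_t", "c4_s", "c4_t", "x0_s", "x0_t"):
            arr = _as_float_array(getattr(self, name), name, n)
            object.__setattr__(self, name, arr)
        if np.any(self.k_s <= 0) or np.any(self.k_t <= 0):
            raise InputError("all force constants must be positive")
        if np.any(self.c4_s < 0) or np.any(self.c4_t < 0):
            raise InputError("quartic coefficients must be non-negative (bound states)")

    @property
    def n_coords(self) -> int:
        return int(self.k_s.size)


@dataclass(frozen=True)
class NoisyEnvironmentParams:
    """Harmonic solute pair plus a common-mode harmonic environment.

    The environment term Σ ½ k_env x² over ``n_env_modes`` extra coordinates
    is *identical* for both spin states, emulating the MM contribution in a
    QM/MM setup: it fluctuates strongly with temperature but cancels exactly
    in E_T − E_S at every configuration.
    """

    solute: HarmonicPairParams
    n_env_modes: int
    env_k: float

    def __post_init__(self) -> None:
        if self.n_env_modes < 1:
            raise InputError("n_env_modes must be >= 1")
        if self.env_k <= 0:
            raise InputError("env_k must be positive")

    @property
    def n_coords(self) -> int:
        return self.solute.n_coords + self.n_env_modes

    def as_harmonic(self) -> HarmonicPairParams:
        """Equivalent plain harmonic pair (environment appended to both states)."""
        n_env = self.n_env_modes
        env_k = np.full(n_env, self.env_k)
        zeros = np.zeros(n_env)
        s = self.solute
        return HarmonicPairParams(
            k_s=np.concatenate([s.k_s, env_k]),
            k_t=np.concatenate([s.k_t, env_k]),
            x0_s=np.concatenate([s.x0_s, zeros]),
            x0_t=np.concatenate([s.x0_t, zeros]),
            e0_s=s.e0_s,
            e0_t=s.e0_t,
        )


@dataclass(frozen=True)
class ExternalStubParams:
    """Contract placeholder for a real QM/MM engine adapter.

    An adapter must supply, for a single nuclear configuration, the energy
    and analytic gradient of both spin states per call.  This backend never
    evaluates; it exists so that configuration files can name an external
    engine and fail loudly rather than silently.
    """

    engine: str = "unspecified"
    n_coords_hint: int = 0

    @property
    def n_coords(self) -> int:
        return self.n_coords_hint


BackendParams = Union[
    HarmonicPairParams, QuarticPairParams, NoisyEnvironmentParams, ExternalStubParams
]

_BACKEND_NAMES = {
    HarmonicPairParams: "harmonic_pair",
    QuarticPairParams: "quartic_pair",
    NoisyEnvironmentParams: "noisy_environment",
    ExternalStubParams: "external_stub",
}


@dataclass(frozen=True)
class MixedHamiltonianSpec:
    """The alchemical state H(λ) = (1−λ)H_S + λH_T."""

    lam: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.lam <= 1.0):
            raise InputError(f"lambda must lie in [0, 1], got {self.lam}")


@dataclass(frozen=True)
class TwoStateSystem:
    """Particle layout plus a two-surface energy backend."""

    n_particles: int
    dim: int
    masses: NDArray[np.float64]
    frozen_mask: NDArray[np.bool_]
    params: BackendParams

    def __post_init__(self) -> None:
        if self.n_particles < 1:
            raise InputError("n_particles must be >= 1")
        if self.dim not in (1, 2, 3):
            raise InputError(f"dim must be 1, 2 or 3, got {self.dim}")
        masses = _as_float_array(self.masses, "masses", self.n_particles)
        if np.any(masses <= 0):
            raise InputError("all masses must be positive")
        object.__setattr__(self, "masses", masses)
        mask = np.asarray(self.frozen_mask, dtype=bool)
        if mask.shape != (self.n_particles,):
            raise InputError("frozen_mask length must equal n_particles")
        object.__setattr__(self, "frozen_mask", mask)
        n_coords = self.n_particles * self.dim
        if not isinstance(self.params, ExternalStubParams) and self.params.n_coords != n_coords:
            raise InputError(
                f"backend defines {self.params.n_coords} coordinates but the "
                f"system has {n_coords} ({self.n_particles} particles × dim {self.dim})"
            )

    @property
    def backend(self) -> str:
        return _BACKEND_NAMES[type(self.params)]

    @property
    def n_coords(self) -> int:
        return self.n_particles * self.dim

    @property
    def coord_masses(self) -> NDArray[np.float64]:
        """Masses expanded to one entry per coordinate."""
        return np.repeat(self.masses, self.dim)

    @property
    def coord_frozen(self) -> NDArray[np.bool_]:
        """Frozen mask expanded to one entry per coordinate."""
        return np.repeat(self.frozen_mask, self.dim)


# ---------------------------------------------------------------------------
# energy evaluation


def _check_coords(system: TwoStateSystem, x) -> NDArray[np.float64]:
    x = np.asarray(x, dtype=float).reshape(-1)
    if x.size != system.n_coords:
        raise InputError(
            f"coordinate vector has {x.size} entries, system expects {system.n_coords}"
        )
    return x


def _harmonic_eg(p: HarmonicPairParams, state: State, x):
    k, x0, e0 = (p.k_s, p.x0_s, p.e0_s) if state == "singlet" else (p.k_t, p.x0_t, p.e0_t)
    d = x - x0
    return e0 + 0.5 * float(np.dot(k, d * d)), k * d


def _quartic_eg(p: QuarticPairParams, state: State, x):
    if state == "singlet":
        k, c4, x0, e0 = p.k_s, p.c4_s, p.x0_s, p.e0_s
    else:
        k, c4, x0, e0 = p.k_t, p.c4_t, p.x0_t, p.e0_t
    d = x - x0
    d2 = d * d
    energy = e0 + 0.5 * float(np.dot(k, d2)) + float(np.dot(c4, d2 * d2))
    grad = k * d + 4.0 * c4 * d2 * d
    return energy, grad


def _noisy_eg(p: NoisyEnvironmentParams, state: State, x):
    ns = p.solute.n_coords
    e_sol, g_sol = _harmonic_eg(p.solute, state, x[:ns])
    x_env = x[ns:]
    e_env = 0.5 * p.env_k * float(np.dot(x_env, x_env))
    return e_sol + e_env, np.concatenate([g_sol, p.env_k * x_env])


def state_energy_gradient(
    system: TwoStateSystem, state: State, x
) -> tuple[float, NDArray[np.float64]]:
    """Potential energy (kJ/mol) and analytic gradient (kJ/mol/Å) of one spin state.

    Gradients are reported for every coordinate, including frozen ones;
    masking is the integrator's responsibility.
    """
    if state not in ("singlet", "triplet"):
        raise InputError(f"state must be 'singlet' or 'triplet', got {state!r}")
    x = _check_coords(system, x)
    p = system.params
    if isinstance(p, HarmonicPairParams):
        return _harmonic_eg(p, state, x)
    if isinstance(p, QuarticPairParams):
        return _quartic_eg(p, state, x)
    if isinstance(p, NoisyEnvironmentParams):
        return _noisy_eg(p, state, x)
    raise UnsupportedBackendError(
        "external_stub backends document the engine contract but cannot be "
        "evaluated; wire in a real adapter"
    )


def mixed_energy_gradient(
    system: TwoStateSystem, spec: MixedHamiltonianSpec, x
) -> tuple[float, NDArray[np.float64], float, float]:
    """Energy and gradient of H(λ), plus the pure-state energies E_S and E_T.

    Both surfaces are evaluated on every call so that each sampled frame
    carries (E_S, E_T, E_mix) and the FEP post-processing never has to
    re-evaluate configurations.  At λ = 0 and λ = 1 the mixed values are
    bit-identical to the corresponding pure state.
    """
    e_s, g_s = state_energy_gradient(system, "singlet", x)
    e_t, g_t = state_energy_gradient(system, "triplet", x)
    lam = spec.lam
    if lam == 0.0:
        return e_s, g_s, e_s, e_t
    if lam == 1.0:
        return e_t, g_t, e_s, e_t
    energy = (1.0 - lam) * e_s + lam * e_t
    grad = (1.0 - lam) * g_s + lam * g_t
    return energy, grad, e_s, e_t


# ---------------------------------------------------------------------------
# free-energy oracles


def analytic_delta_f(params: HarmonicPairParams, temperature: float) -> float:
    """Closed-form configurational ΔF (triplet − singlet) of a harmonic pair.

    For classical harmonic wells the partition function factorises per
    coordinate, giving

        ΔF = (E0_T − E0_S) + (k_B T / 2) Σ_i ln(k_T,i / k_S,i);

    the minima positions drop out.
    """
    if not isinstance(params, HarmonicPairParams):
        raise UnsupportedBackendError("analytic ΔF is defined for harmonic pairs only")
    kbt = kt(temperature)
    return (params.e0_t - params.e0_s) + 0.5 * kbt * float(np.sum(np.log(params.k_t / params.k_s)))


def quadrature_delta_f(
    system: TwoStateSystem,
    temperature: float,
    span_sigmas: float = 10.0,
    n_points: int = 4001,
) -> float:
    """Brute-force ΔF = −k_B T ln(Z_T/Z_S) by direct quadrature.

    Restricted to systems with at most two coordinates.  The grid covers
    ``span_sigmas`` thermal standard deviations (from the *softer* force
    constant) around both minima; if the Boltzmann weight at the grid edge
    exceeds 1e-10 of the maximum, the grid is judged too narrow and an
    :class:`AccuracyError` is raised.
    """
    if system.n_coords > 2:
        raise InputError("quadrature oracle supports at most 2 coordinates")
    if system.backend == "external_stub":
        raise UnsupportedBackendError("cannot integrate an external stub")
    kbt = kt(temperature)

    p = system.params
    if isinstance(p, NoisyEnvironmentParams):
        p = p.as_harmonic()
    # Softest curvature sets the widest thermal width; centre on both minima.
    k_min = np.minimum(p.k_s, p.k_t)
    sigma = np.sqrt(kbt / k_min)
    lo = np.minimum(p.x0_s, p.x0_t) - span_sigmas * sigma
    hi = np.maximum(p.x0_s, p.x0_t) + span_sigmas * sigma

    axes = [np.linspace(lo[i], hi[i], n_points) for i in range(system.n_coords)]
    if system.n_coords == 1:
        pts = axes[0][:, None]
    else:
        g0, g1 = np.meshgrid(axes[0], axes[1], indexing="ij")
        pts = np.column_stack([g0.ravel(), g1.ravel()])

    log_z = {}
    for st in ("singlet", "triplet"):
        energies = np.array([state_energy_gradient(system, st, q)[0] for q in pts])
        w = -energies / kbt
        w_max = w.max()
        if system.n_coords == 1:
            edge = max(w[0], w[-1])
        else:
            wg = w.reshape(n_points, n_points)
            edge = max(wg[0].max(), wg[-1].max(), wg[:, 0].max(), wg[:, -1].max())
        if edge - w_max > np.log(1e-10):
            raise AccuracyError(
                "quadrature grid too narrow: boundary Boltzmann weight "
                f"{np.exp(edge - w_max):.2e} of the maximum"
            )
        dens = np.exp(w - w_max)
        if system.n_coords == 1:
            z = np.trapezoid(dens[:, 0] if dens.ndim > 1 else dens, axes[0])
        else:
            z = np.trapezoid(np.trapezoid(dens.reshape(n_points, n_points), axes[1], axis=1), axes[0])
        log_z[st] = np.log(z) + w_max

    return -kbt * (log_z["triplet"] - log_z["singlet"])


# ---------------------------------------------------------------------------
# TOML serialization

_PARAM_FIELDS = {
    "harmonic_pair": ("k_s", "k_t", "x0_s", "x0_t", "e0_s", "e0_t"),
    "quartic_pair": ("k_s", "k_t", "c4_s", "c4_t", "x0_s", "x0_t", "e0_s", "e0_t"),
}


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    if isinstance(v, (float, np.floating)):
        return repr(float(v))
    if isinstance(v, str):
        return f'"{v}"'
    return "[" + ", ".join(_toml_value(x) for x in v) + "]"


def system_to_toml(system: TwoStateSystem) -> str:
    """Serialize a system definition to TOML text (format ``spinfep-system-v1``)."""
    lines = [f'format = "{SYSTEM_FORMAT}"', "", "[system]"]
    lines.append(f"n_particles = {system.n_particles}")
    lines.append(f"dim = {system.dim}")
    lines.append(f"masses = {_toml_value(system.masses)}")
    lines.append(f"frozen = {_toml_value(list(map(bool, system.frozen_mask)))}")
    lines.append(f'backend = "{system.backend}"')
    lines.append("")
    lines.append("[system.params]")
    p = system.params
    if system.backend in _PARAM_FIELDS:
        for name in _PARAM_FIELDS[system.backend]:
            lines.append(f"{name} = {_toml_value(getattr(p, name))}")
    elif system.backend == "noisy_environment":
        assert isinstance(p, NoisyEnvironmentParams)
        lines.append(f"n_env_modes = {p.n_env_modes}")
        lines.append(f"env_k = {_toml_value(p.env_k)}")
        lines.append("")
        lines.append("[system.params.solute]")
        for name in _PARAM_FIELDS["harmonic_pair"]:
            lines.append(f"{name} = {_toml_value(getattr(p.solute, name))}")
    else:
        assert isinstance(p, ExternalStubParams)
        lines.append(f'engine = "{p.engine}"')
        lines.append(f"n_coords_hint = {p.n_coords_hint}")
    return "\n".join(lines) + "\n"


def _params_from_dict(backend: str, d: dict) -> BackendParams:
    if backend == "harmonic_pair":
        return HarmonicPairParams(**{k: d[k] for k in _PARAM_FIELDS["harmonic_pair"]})
    if backend == "quartic_pair":
        return QuarticPairParams(**{k: d[k] for k in _PARAM_FIELDS["quartic_pair"]})
    if backend == "noisy_environment":
        solute = HarmonicPairParams(
            **{k: d["solute"][k] for k in _PARAM_FIELDS["harmonic_pair"]}
        )
        return NoisyEnvironmentParams(
            solute=solute, n_env_modes=int(d["n_env_modes"]), env_k=float(d["env_k"])
        )
    if backend == "external_stub":
        return ExternalStubParams(
            engine=d.get("engine", "unspecified"),
            n_coords_hint=int(d.get("n_coords_hint", 0)),
        )
    raise InputError(f"unknown backend {backend!r}")


def system_from_toml(text: str) -> TwoStateSystem:
    """Parse a system definition from TOML text."""
    doc = tomllib.loads(text)
    if doc.get("format") != SYSTEM_FORMAT:
        raise InputError(
            f"unrecognised system file format {doc.get('format')!r}; expected {SYSTEM_FORMAT!r}"
        )
    sysd = doc["system"]
    params = _params_from_dict(sysd["backend"], sysd.get("params", {}))
    return TwoStateSystem(
        n_particles=int(sysd["n_particles"]),
        dim=int(sysd["dim"]),
        masses=sysd["masses"],
        frozen_mask=sysd["frozen"],
        params=params,
    )


def load_system(path: str | Path) -> TwoStateSystem:
    return system_from_toml(Path(path).read_text())


def save_system(system: TwoStateSystem, path: str | Path) -> None:
    Path(path).write_text(system_to_toml(system))
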