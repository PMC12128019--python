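"""Sampling configurations of H(λ) at fixed temperature.

Two samplers share one output contract (:class:`EnergySeries`):

* :func:`run_window` — Langevin molecular dynamics with the BAOAB splitting,
  propagating on the λ-mixed surface.  BAOAB is used because its
  configurational averages are accurate at moderate time steps, which is
  what an FEP estimate consumes.  With ``friction = 0`` the O-step becomes
  the identity and the scheme reduces to velocity Verlet (NVE diagnostic
  mode).
* :func:`direct_canonical_sample` — exact independent draws from the
  canonical distribution of H(λ), available for harmonic backends where the
  λ-mix of quadratics is itself quadratic.  It provides an uncorrelated
  ground truth against which the MD sampler is checked.

Frozen particles emulate the frozen outer shells of a large-system setup:
their velocities are pinned to zero and their coordinates never change, and
they are excluded from kinetic-temperature accounting.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from numpy.typing import NDArray

from .constants import ENERGY_PER_INTERNAL, KB, kt
from .errors import DivergenceError, InputError, UnsupportedBackendError
from .systems import (
    HarmonicPairParams,
    MixedHamiltonianSpec,
    NoisyEnvironmentParams,
    TwoStateSystem,
    mixed_energy_gradient,
)

_MIX_TOL = 1e-9


@dataclass(frozen=True)
class MDConfig:
    """Langevin MD run parameters.

    dt is in fs, friction in ps^-1, temperature in K.  The first ``n_equil``
    steps are discarded as equilibration and every ``record_stride``-th
    remaining step is recorded.
    """

    dt: float = 1.0
    n_steps: int = 10_000
    n_equil: int = 1_000
    temperature: float = 300.0
    friction: float = 1.0
    seed: int = 0
    record_stride: int = 1
    record_coordinates: bool = False
    record_velocities: bool = False

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise InputError("dt must be positive")
        if not (self.n_steps > self.n_equil >= 0):
            raise InputError("need n_steps > n_equil >= 0")
        if self.temperature <= 0:
            raise InputError("temperature must be positive")
        if self.friction < 0:
            raise InputError("friction must be non-negative")
        if self.record_stride < 1:
            raise InputError("record_stride must be >= 1")


@dataclass
class EnergySeries:
    """Per-frame (E_S, E_T, E_mix) record from one window's sampling."""

    lam: float
    steps: NDArray[np.int64]
    e_s: NDArray[np.float64]
    e_t: NDArray[np.float64]
    e_mix: NDArray[np.float64]
    temperature: float
    seed: int
    coordinates: Optional[NDArray[np.float64]] = None  # (n_frames, n_coords)
    velocities: Optional[NDArray[np.float64]] = None

    def __post_init__(self) -> None:
        for name in ("steps", "e_s", "e_t", "e_mix"):
            setattr(self, name, np.asarray(getattr(self, name)))
        n = self.steps.size
        if not (self.e_s.size == self.e_t.size == self.e_mix.size == n):
            raise InputError("all frame columns must have equal length")
        if n and np.any(np.diff(self.steps) <= 0):
            raise InputError("frames must be ordered by step")
        expected = (1.0 - self.lam) * self.e_s + self.lam * self.e_t
        scale = 1.0 + np.abs(self.e_mix)
        if n and np.max(np.abs(self.e_mix - expected) / scale) > _MIX_TOL:
            raise InputError("E_mix inconsistent with (1-λ)E_S + λE_T")

    def __len__(self) -> int:
        return int(self.steps.size)


# ---------------------------------------------------------------------------
# Langevin MD


def window_rng(master_seed: int, lam_index: int) -> np.random.Generator:
    """Independent, reproducible random stream for one λ window.

    Streams are derived counter-style from (master seed, window index) via
    :class:`numpy.random.SeedSequence` spawn keys, so windows can run in any
    order or in parallel and still reproduce bit-identically.
    """
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(lam_index,)))


def _starting_coords(system: TwoStateSystem, lam: float) -> NDArray[np.float64]:
    p = system.params
    if isinstance(p, NoisyEnvironmentParams):
        p = p.as_harmonic()
    if isinstance(p, HarmonicPairParams):
        k_eff = (1.0 - lam) * p.k_s + lam * p.k_t
        return ((1.0 - lam) * p.k_s * p.x0_s + lam * p.k_t * p.x0_t) / k_eff
    if hasattr(p, "x0_s"):
        return np.asarray((1.0 - lam) * p.x0_s + lam * p.x0_t, dtype=float)
    return np.zeros(system.n_coords)


def run_window(
    system: TwoStateSystem,
    spec: MixedHamiltonianSpec,
    config: MDConfig,
    rng: np.random.Generator | None = None,
    x0: NDArray[np.float64] | None = None,
) -> EnergySeries:
    """Sample H(λ) with BAOAB Langevin dynamics.

    Deterministic for a given ``config.seed`` (or an explicitly supplied
    generator).  Raises :class:`DivergenceError`, naming the step, if the
    energy or force becomes non-finite.
    """
    if system.backend == "external_stub":
        raise UnsupportedBackendError("cannot propagate an external stub backend")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    lam = spec.lam
    n_coords = system.n_coords
    masses = system.coord_masses
    mobile = ~system.coord_frozen

    kbt_int = kt(config.temperature) / ENERGY_PER_INTERNAL  # amu Å²/fs²
    dt = config.dt
    gamma = config.friction * 1e-3  # ps^-1 -> fs^-1

    x = np.array(_starting_coords(system, lam) if x0 is None else x0, dtype=float)
    if x.size != n_coords:
        raise InputError("x0 has wrong length")
    v = np.zeros(n_coords)
    sigma_v = np.sqrt(kbt_int / masses)
    v[mobile] = rng.standard_normal(int(mobile.sum())) * sigma_v[mobile]

    if gamma > 0:
        c1 = np.exp(-gamma * dt)
        c2 = np.sqrt(1.0 - c1 * c1)
    else:
        c1, c2 = 1.0, 0.0

    energy, grad, e_s, e_t = mixed_energy_gradient(system, spec, x)
    force = -grad / ENERGY_PER_INTERNAL  # amu Å / fs²

    steps, es_l, et_l, em_l = [], [], [], []
    coords_l: list[NDArray[np.float64]] = []
    vel_l: list[NDArray[np.float64]] = []

    half = 0.5 * dt
    for step in range(1, config.n_steps + 1):
        # B
        v[mobile] += half * force[mobile] / masses[mobile]
        # A
        x[mobile] += half * v[mobile]
        # O
        if c2 > 0.0:
            v[mobile] = c1 * v[mobile] + c2 * sigma_v[mobile] * rng.standard_normal(
                int(mobile.sum())
            )
        # A
        x[mobile] += half * v[mobile]
        with np.errstate(over="ignore", invalid="ignore"):
            energy, grad, e_s, e_t = mixed_energy_gradient(system, spec, x)
        if not (np.isfinite(energy) and np.all(np.isfinite(grad))):
            raise DivergenceError(f"non-finite energy or force at step {step}")
        force = -grad / ENERGY_PER_INTERNAL
        # B
        v[mobile] += half * force[mobile] / masses[mobile]

        if step > config.n_equil and (step - config.n_equil - 1) % config.record_stride == 0:
            steps.append(step)
            es_l.append(e_s)
            et_l.append(e_t)
            em_l.append(energy)
            if config.record_coordinates:
                coords_l.append(x.copy())
            if config.record_velocities:
                vel_l.append(v.copy())

    return EnergySeries(
        lam=lam,
        steps=np.array(steps, dtype=np.int64),
        e_s=np.array(es_l),
        e_t=np.array(et_l),
        e_mix=np.array(em_l),
        temperature=config.temperature,
        seed=config.seed,
        coordinates=np.array(coords_l) if config.record_coordinates else None,
        velocities=np.array(vel_l) if config.record_velocities else None,
    )


# ---------------------------------------------------------------------------
# exact canonical sampling (harmonic backends)


def direct_canonical_sample(
    system: TwoStateSystem,
    spec: MixedHamiltonianSpec,
    temperature: float,
    n: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    return_coords: bool = False,
) -> EnergySeries:
    """n independent exact draws from the canonical ensemble of H(λ).

    A λ-mix of per-coordinate quadratics is quadratic, with effective force
    constant k_eff = (1−λ)k_S + λk_T and a shifted minimum, so each mobile
    coordinate is an independent Gaussian with variance k_B T / k_eff.
    Frozen coordinates are pinned at the mixed minimum.  Harmonic backends
    only (including the effectively harmonic noisy-environment system).
    """
    params = system.params
    if isinstance(params, NoisyEnvironmentParams):
        params = params.as_harmonic()
    if not isinstance(params, HarmonicPairParams):
        raise UnsupportedBackendError("direct canonical sampling needs a harmonic backend")
    if n < 1:
        raise InputError("n must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    kbt = kt(temperature)
    lam = spec.lam

    k_eff = (1.0 - lam) * params.k_s + lam * params.k_t
    x_min = ((1.0 - lam) * params.k_s * params.x0_s + lam * params.k_t * params.x0_t) / k_eff
    sigma = np.sqrt(kbt / k_eff)
    mobile = ~system.coord_frozen
    xs = np.tile(x_min, (n, 1))
    xs[:, mobile] += rng.standard_normal((n, int(mobile.sum()))) * sigma[mobile]

    # vectorised per-coordinate harmonic energies on both surfaces
    ds = xs - params.x0_s
    dt_ = xs - params.x0_t
    e_s = params.e0_s + 0.5 * (ds * ds) @ params.k_s
    e_t = params.e0_t + 0.5 * (dt_ * dt_) @ params.k_t
    e_mix = (1.0 - lam) * e_s + lam * e_t

    return EnergySeries(
        lam=lam,
        steps=np.arange(1, n + 1, dtype=np.int64),
        e_s=e_s,
        e_t=e_t,
        e_mix=e_mix,
        temperature=temperature,
        seed=-1 if seed is None else seed,
        coordinates=xs if return_coords else None,
    )


# ---------------------------------------------------------------------------
# diagnostics


def kinetic_temperature(
    velocities: NDArray[np.float64],
    masses: NDArray[np.float64],
    frozen_mask: NDArray[np.bool_] | None = None,
    dim: int = 1,
) -> tuple[NDArray[np.float64], float]:
    """Instantaneous and mean kinetic temperature over mobile degrees of freedom.

    ``velocities`` has shape (n_frames, n_coords) in Å/fs; ``masses`` is per
    particle (amu) and ``frozen_mask`` per particle.  Frozen particles are
    excluded from the average regardless of any stored velocity.
    """
    v = np.atleast_2d(np.asarray(velocities, dtype=float))
    masses = np.asarray(masses, dtype=float)
    n_particles = masses.size
    if v.shape[1] != n_particles * dim:
        raise InputError("velocity width must equal n_particles * dim")
    if frozen_mask is None:
        frozen_mask = np.zeros(n_particles, dtype=bool)
    frozen_mask = np.asarray(frozen_mask, dtype=bool)
    mobile = np.repeat(~frozen_mask, dim)
    n_dof = int(mobile.sum())
    if n_dof == 0:
        raise InputError("all particles frozen: kinetic temperature undefined")
    m_coord = np.repeat(masses, dim)
    ke = 0.5 * (v[:, mobile] ** 2 * m_coord[mobile]).sum(axis=1) * ENERGY_PER_INTERNAL
    t_inst = 2.0 * ke / (n_dof * KB)
    return t_inst, float(t_inst.mean())


# ---------------------------------------------------------------------------
# TSV I/O

_TSV_COLUMNS = ["step", "E_S", "E_T", "E_mix"]


def write_series_tsv(series: EnergySeries, path: str | Path) -> None:
    """Write an energy series as tab-separated text with a metadata header."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(
            f"# lambda={series.lam!r} temperature={series.temperature!r} seed={series.seed}\n"
        )
        fh.write("\t".join(_TSV_COLUMNS) + "\n")
        df = pd.DataFrame(
            {"step": series.steps, "E_S": series.e_s, "E_T": series.e_t, "E_mix": series.e_mix}
        )
        df.to_csv(fh, sep="\t", header=False, index=False, float_format="%.12g")


def read_series_tsv(path: str | Path) -> EnergySeries:
    """Read an energy series written by :func:`write_series_tsv`."""
    path = Path(path)
    text = path.read_text()
    first, _, rest = text.partition("\n")
    if not first.startswith("#"):
        raise InputError(f"{path}: missing metadata header line")
    meta = dict(tok.split("=", 1) for tok in first.lstrip("# ").split())
    try:
        lam = float(meta["lambda"])
        temperature = float(meta["temperature"])
        seed = int(meta["seed"])
    except (KeyError, ValueError) as exc:
        raise InputError(f"{path}: malformed metadata header: {first!r}") from exc
    df = pd.read_csv(io.StringIO(rest), sep="\t")
    missing = set(_TSV_COLUMNS) - set(df.columns)
    if missing:
        raise InputError(f"{path}: missing columns {sorted(missing)}")
    return EnergySeries(
        lam=lam,
        steps=df["step"].to_numpy(np.int64),
        e_s=df["E_S"].to_numpy(float),
        e_t=df["E_T"].to_numpy(float),
        e_mix=df["E_mix"].to_numpy(float),
        temperature=temperature,
        seed=seed,
    )


def write_xyz(
    coordinates: NDArray[np.float64],
    path: str | Path,
    elements: list[str] | None = None,
    comment: str = "",
) -> None:
    """Write a (n_frames, n_atoms*3) coordinate array as a standard XYZ trajectory."""
    coords = np.atleast_2d(np.asarray(coordinates, dtype=float))
    if coords.shape[1] % 3 != 0:
        raise InputError("XYZ output requires 3 coordinates per atom")
    n_atoms = coords.shape[1] // 3
    if elements is None:
        elements = ["X"] * n_atoms
    if len(elements) != n_atoms:
        raise InputError("one element label per atom required")
    with open(path, "w") as fh:
        for frame in coords:
            fh.write(f"{n_atoms}\n{comment}\n")
            for el, (px, py, pz) in zip(elements, frame.reshape(-1, 3)):
                fh.write(f"{el} {px:.8f} {py:.8f} {pz:.8f}\n")
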