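"""Synthetic two-state systems and calibrated random series for validation.

Every fixture is reproducible from its parameters and a seed, and carries
its own oracle (a closed-form ΔF, a known AR(1) coefficient, known Gaussian
moments) so tests never compare against values the code under test
produced.

The noisy-environment fixture is the package's scaled-down analogue of a
QM/MM setup: a small harmonic "solute" whose two electronic surfaces
differ, embedded in a bath of harmonic environment modes whose energy is
identical for both states.  At temperature T each harmonic mode contributes
potential-energy variance (k_B T)²/2, so n modes give an instantaneous
environment-energy SD of k_B T √(n/2); the mode count is chosen to hit a
requested SD.  The default target of 40 kJ/mol at 300 K puts the endpoint
ΔU error in the tens of kJ/mol while the FEP error — from which the
common-mode term cancels exactly — stays at tenths or below.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import kt
from .errors import InputError, ParameterError
from .systems import HarmonicPairParams, NoisyEnvironmentParams, TwoStateSystem, analytic_delta_f

#: default environment-energy SD (kJ/mol), of the order of the data SD a
#: fluctuating MM environment imposes on endpoint energy averages.
DEFAULT_ENV_SD = 40.0

_MAX_ENV_MODES = 100_000


@dataclass(frozen=True)
class NoisyEnvironmentSpec:
    """Recipe for a common-mode-noise two-state system."""

    solute: HarmonicPairParams
    env_k: float = 500.0
    target_env_sd: float = DEFAULT_ENV_SD

    def __post_init__(self) -> None:
        if self.target_env_sd <= 0:
            raise ParameterError("target_env_sd must be positive")
        if self.env_k <= 0:
            raise ParameterError("env_k must be positive")


def make_harmonic_pair(
    delta_e0: float = 10.0,
    k_ratio: float | np.ndarray = 1.0,
    n_coords: int = 1,
    seed: int | None = None,
    k_base: float = 300.0,
    x0_shift: float = 0.1,
    mass: float = 12.0,
) -> tuple[TwoStateSystem, float]:
    """Harmonic two-state system with a closed-form ΔF oracle.

    ``k_ratio`` sets k_T/k_S (scalar, or per coordinate); with a seed, the
    per-coordinate ratios are drawn log-uniformly in [1, k_ratio] and the
    minima of the triplet surface are offset by up to ``x0_shift`` Å (minima
    offsets do not affect the harmonic ΔF).  Returns (system, ΔF at 300 K).
    """
    rng = np.random.default_rng(seed)
    k_s = np.full(n_coords, k_base)
    if seed is not None and np.isscalar(k_ratio) and k_ratio != 1.0:
        if k_ratio < 1.0:
            raise InputError("scalar k_ratio must be >= 1 when drawn randomly")
        ratios = np.exp(rng.uniform(0.0, np.log(k_ratio), n_coords))
        shifts = rng.uniform(-x0_shift, x0_shift, n_coords)
    else:
        ratios = np.broadcast_to(np.asarray(k_ratio, dtype=float), (n_coords,)).copy()
        shifts = np.full(n_coords, x0_shift)
    params = HarmonicPairParams(
        k_s=k_s,
        k_t=k_s * ratios,
        x0_s=np.zeros(n_coords),
        x0_t=shifts,
        e0_s=0.0,
        e0_t=delta_e0,
    )
    system = TwoStateSystem(
        n_particles=n_coords,
        dim=1,
        masses=np.full(n_coords, mass),
        frozen_mask=np.zeros(n_coords, dtype=bool),
        params=params,
    )
    return system, analytic_delta_f(params, 300.0)


def env_modes_for_sd(target_sd: float, temperature: float) -> int:
    """Number of harmonic modes whose total PE fluctuation SD is ``target_sd``.

    Each classical harmonic mode's potential energy is (k_B T/2)·χ²₁ with
    variance (k_B T)²/2, so n modes give SD k_B T √(n/2).
    """
    kbt = kt(temperature)
    n = int(round(2.0 * (target_sd / kbt) ** 2))
    if n < 1:
        n = 1
    if n > _MAX_ENV_MODES:
        raise ParameterError(
            f"target SD {target_sd} kJ/mol needs {n} environment modes (cap {_MAX_ENV_MODES})"
        )
    realized = kbt * np.sqrt(n / 2.0)
    if abs(realized - target_sd) / target_sd > 0.05:
        raise ParameterError(
            f"cannot realise environment SD {target_sd} kJ/mol within 5% "
            f"(closest achievable: {realized:.3f} with {n} modes)"
        )
    return n


def make_noisy_environment(
    spec: NoisyEnvironmentSpec | None = None, temperature: float = 300.0
) -> TwoStateSystem:
    """Two-state system whose environment energy is common-mode by construction.

    The environment term enters E_S and E_T identically, so E_T − E_S is
    independent of the environment coordinates at every configuration.
    """
    if spec is None:
        spec = NoisyEnvironmentSpec(solute=default_noisy_solute())
    n_env = env_modes_for_sd(spec.target_env_sd, temperature)
    params = NoisyEnvironmentParams(solute=spec.solute, n_env_modes=n_env, env_k=spec.env_k)
    n_particles = params.n_coords
    return TwoStateSystem(
        n_particles=n_particles,
        dim=1,
        masses=np.full(n_particles, 12.0),
        frozen_mask=np.zeros(n_particles, dtype=bool),
        params=params,
    )


def default_noisy_solute() -> HarmonicPairParams:
    """Default solute for the noisy-environment fixture.

    A single coordinate whose triplet surface sits ~300 kJ/mol above the
    singlet (the scale of a nucleobase singlet–triplet gap), is 25% softer,
    and has its minimum displaced by 0.1 Å.
    """
    return HarmonicPairParams(
        k_s=np.array([400.0]),
        k_t=np.array([300.0]),
        x0_s=np.array([0.0]),
        x0_t=np.array([0.1]),
        e0_s=0.0,
        e0_t=300.0,
    )


# ---------------------------------------------------------------------------
# calibrated random series


def generate_ar1(rho: float, n: int, seed: int | None = None, sigma: float = 1.0,
                 mu: float = 0.0) -> np.ndarray:
    """Stationary AR(1) series with lag-1 autocorrelation ``rho``.

    x_t = μ + ρ(x_{t−1} − μ) + √(1−ρ²) σ ξ_t, initialised from the
    stationary distribution N(μ, σ²) so no burn-in is needed.
    """
    if not (-1.0 < rho < 1.0):
        raise InputError("|rho| must be < 1")
    if sigma < 0:
        raise InputError("sigma must be non-negative")
    if n < 1:
        raise InputError("n must be >= 1")
    rng = np.random.default_rng(seed)
    innov = rng.standard_normal(n) * sigma
    x = np.empty(n)
    x[0] = innov[0]
    c = np.sqrt(1.0 - rho * rho)
    for t in range(1, n):
        x[t] = rho * x[t - 1] + c * innov[t]
    return mu + x


def generate_gaussian_dh(
    mu: float, sigma: float, n: int, seed: int | None = None
) -> np.ndarray:
    """IID Gaussian ΔH samples (kJ/mol), ready for a WindowRecord."""
    if sigma < 0:
        raise InputError("sigma must be non-negative")
    if n < 1:
        raise InputError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return mu + sigma * rng.standard_normal(n)
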