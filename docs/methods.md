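# Methods

## Model and estimators

spinfep computes the free-energy difference between two electronic states
sharing one set of nuclei. The alchemical Hamiltonian is the linear mix
H(λ) = (1−λ)H_S + λH_T of the two potential-energy surfaces; kinetic energy
is state-independent (the nuclei and masses do not change with spin state),
so it cancels identically in every ΔH and only configurational free-energy
differences are ever formed. Absolute free energies are never computed.

Per window pair (λ_i → λ_j) the estimator is the forward Zwanzig average
ΔG = −k_BT ln⟨e^{−ΔH/k_BT}⟩_i with ΔH = (λ_j − λ_i)(E_T − E_S), evaluated
in log-sum-exp form (shift by min ΔH) so that samples with |ΔH| up to
~10⁴ kJ/mol neither overflow nor underflow; a constant series returns the
constant exactly. Backward series are computed only for the overlap
diagnostic. The total ΔG is the exact sum over a strictly increasing λ
schedule covering [0, 1]; the default schedule is {0, 0.2, 0.4, 0.6, 0.8, 1}
(four alchemical intermediates).

### Error model

The per-window error is the first-order propagation of the standard error
of m = ⟨X⟩, X = e^{−ΔH/k_BT}, through −k_BT ln m:

* δε² = ((1+2τ)/N) · Var(X), with Var(X) = ⟨X²⟩ − ⟨X⟩² the (population)
  sample variance;
* ε = k_BT · δε / m;
* the sampling ratio 1+2τ = (1+r₁)/(1−r₁), with r₁ the lag-1
  autocorrelation of the X series, clamped inside (−1, 1) by 1e−12.

Three choices here were genuinely open and are worth stating:

* **Which series carries r₁.** The error chain concerns the mean of X, so
  the autocorrelation is measured on the X (Boltzmann-factor) series, not
  on ΔH. Both r₁ and the ratio Var(X)/m² are invariant under the max-shift,
  so the whole computation stays in safe floating-point range.
* **The variance form.** `chipot_error` implements ⟨X²⟩ − ⟨X⟩². A literal
  alternative reading, ⟨X⟩ − ⟨X⟩², is dimensionally inconsistent for a
  variance but is kept behind `variance_form="printed"` purely for
  comparison, isolated in that one function.
* **Placement of ⟨X⟩ in ε.** ε = k_BT δε/⟨X⟩ is the standard first-order
  result (d(−kT ln m)/dm = −kT/m); the multiplicative alternative is
  available as `eps_form="multiply"` for comparison only.

Cross-window errors combine in quadrature (√Σε²): each window is sampled
from its own independent trajectory/stream. A zero-variance window has
ε = 0 and r₁ = 0 by convention (a constant series carries no correlation
information). Error estimates require N ≥ 2; r₁ requires N ≥ 3, below
which it is taken as 0.

The replicate-calibration tests show mean ε within a factor ~1.5 of the
true replicate SD for IID windows and within a factor 2 under AR(1)
correlation ρ = 0.8, where the sampling ratio inflates ε by ≈ √9 = 3. The
lag-1 model is exact for AR(1)-like decay; it will under-correct series
with long non-exponential tails, which is the usual failure mode of
inefficiency estimates from short lags.

### ΔU baseline

ΔU = ⟨U⟩_{λ=1} − ⟨U⟩_{λ=0} from two independent endpoint ensembles, each
state's own Hamiltonian on its own frames, 100 frames per state by default.
The quoted error is the SD of the raw per-frame data (ddof = 1), combined
in quadrature across the two ensembles — deliberately *not* the standard
error of the mean, since that is how this baseline is conventionally
reported. It therefore carries the full environment-energy fluctuation
that FEP cancels.

## Sampling

* **Langevin MD** uses the BAOAB splitting: it gives accurate
  configurational averages at moderate time steps, which is what the
  estimator consumes. Defaults: dt = 1 fs, friction γ = 1 ps⁻¹, T = 300 K,
  equilibration discard 10% of the run. With γ = 0 the O-step is the
  identity and the integrator reduces to velocity Verlet, used as the NVE
  diagnostic (measured drift on a harmonic system at dt = 0.2 fs:
  ~2.5×10⁻⁵ relative over 10⁵ steps). Velocities start from
  Maxwell–Boltzmann at the target temperature; coordinates start at the
  λ-mixed minimum where one is defined.
* **Frozen particles** have their velocities pinned to zero and never move
  — not merely unforced — and are excluded from kinetic-temperature
  accounting, so "frozen shell" semantics are exact and the thermostat
  diagnostic is well-defined on the mobile subset.
* **Exact canonical draws** exploit that an affine mix of per-coordinate
  quadratics is quadratic: each mobile coordinate is Gaussian with
  k_eff = (1−λ)k_S + λk_T and variance k_BT/k_eff. This sampler is the
  uncorrelated ground truth the MD route is tested against.
* **Random streams** are derived counter-style from (master seed, window
  index) via `SeedSequence` spawn keys, so windows reproduce independently
  and in parallel.

Units are fixed globally: kJ/mol, Å, amu, K, fs, with
k_B = 0.00831446 kJ mol⁻¹ K⁻¹ as the single constant source. Internally the
integrator uses amu·Å²/fs² (= 10⁴ kJ/mol) and converts at the boundary.

## Synthetic systems and what they do (not) show

The validation backends are deliberately minimal:

* **Harmonic pairs** have the closed form
  ΔF = ΔE0 + (k_BT/2)Σ ln(k_T/k_S) (minima positions drop out), checked
  against a brute-force quadrature of Z on a grid (≤ 2 coordinates; the
  grid must hold the boundary Boltzmann weight below 1e−10 of the maximum
  or an accuracy error is raised).
* **Quartic pairs** exercise non-Gaussian ΔH distributions and the
  finite-difference gradient checks; their ΔF regression value comes from
  the quadrature oracle.
* **The noisy-environment system** adds n harmonic modes whose energy
  enters both states identically. At temperature T each mode's potential
  energy is (k_BT/2)χ²₁ with variance (k_BT)²/2, so n = 2(SD/k_BT)² modes
  realise a requested energy SD; the default 40 kJ/mol at 300 K (≈514
  modes) puts the ΔU error in the tens of kJ/mol — the scale typical of
  fluctuating-environment endpoint averages — while the solute (one
  coordinate, a ~300 kJ/mol electronic gap, 25% softer triplet well,
  0.1 Å displaced minimum) keeps the FEP error at the 0.01–0.1 kJ/mol
  level. The measured contrast, median log₁₀(SD_ΔU/ε_FEP) ≈ 3.2 over ten
  seeds, is produced by `scripts/acceptance.py`.

These systems are separable, classical and at most mildly anharmonic. They
validate the *statistics* — estimator correctness, error calibration,
common-mode cancellation, sampler equivalence — not the physics of any real
chromophore: passing tests say nothing about force-field or
electronic-structure accuracy, phase-space overlap of real spin surfaces,
or sampling of slow environmental degrees of freedom.

## Problem sizes

Test and acceptance runs use 2000–5000 samples per window (exact draws) or
2×10⁴ MD steps per window, 100 endpoint frames for ΔU, 100 seeds for
coverage counts and 200 replicates for error calibration — sizes at which
every oracle comparison is decisively resolved on a single CPU in seconds
to a couple of minutes.

## Spin-localization classifier

Per-atom Mulliken spin populations (summing to 2 for a triplet, tolerance
±0.05) are summed over user-assigned fragments; the localization index is
the dominant fragment's share of the total spin and the state is called
localized at index ≥ 0.75 (configurable). The threshold is a convention —
the regimes seen in practice sit near 1.0 and near 0.5, so any cutoff with
margin on both sides gives the same labels; 0.75 is the midpoint.
Classification is invariant under atom reordering and monotone in the
dominant share. No electronic-structure parsing is attempted: input is a
plain (atom, spin, fragment) table.

## Known limitations

* Forward-only Zwanzig estimation; no BAR/MBAR reweighting or
  thermodynamic integration. Poor overlap shows up in the
  forward/backward diagnostic and in sampling-ratio warnings rather than
  being repaired.
* The lag-1 inefficiency estimate under-corrects long-memory series.
* Exact sampling exists only for (effectively) harmonic backends; MD is
  the general route.
* No constraints, barostats, periodic boundaries or multiple time
  stepping; the MD is a sampler for model surfaces, not a general
  simulation engine.
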