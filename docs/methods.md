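# Methods

## Generalized modes from velocity covariance

The analysis object is the mass-weighted velocity vector q̇(t) with the fixed
flattening convention index = 3a + k (atom a, component k ∈ {x, y, z}), built
from trajectories in Å/fs with masses in amu. The covariance matrix

K_ij = (1/T) Σ_t q̇_i(t) q̇_j(t)

is the **raw second moment**, not the mean-centred covariance: the defining
relation of the method is the time average of the velocity product itself, and
for a bound system (or after centre-of-mass removal) the mean velocity is ~0,
so the distinction is immaterial in practice but the literal definition is the
one implemented. K is symmetrized as (K + Kᵀ)/2 against accumulation rounding
and validated to be numerically PSD (eigenvalue floor −1e−10·tr K/3N, clamped
to zero).

Diagonalization uses `numpy.linalg.eigh`. Modes are ordered by descending
eigenvalue (velocity variance, i.e. twice the mode's mean kinetic energy);
a stable re-sort by assigned frequency is available as a view, since eigenvalue
order is intrinsic but frequency order is what one browses. Sign convention:
each eigenvector's largest-magnitude component is made positive, which makes
composition reports reproducible across platforms. Eigenvalues that coincide
within 1e−8 relative are reported as degenerate blocks; within such a block
individual eigenvector directions are arbitrary and only subspace statements
are meaningful (the tests compare subspaces, not vectors, there).

Mode frequencies are assigned as the global maximum of the power spectrum of
each projected velocity Q̇_α(t): unbiased autocorrelation to lag T/2, a Hann
half-window taper, ×4 zero padding, cosine transform, clipped at zero. Hann is
the default because truncation ringing of an untapered autocorrelation
produces sidebands that mimic transient structure. A zero-variance mode gets
frequency NaN. If the window supports a coarser resolution than requested, a
`ResolutionWarning` is recorded and the assignment proceeds.

Centre-of-mass translation removal is **offered but off by default** (and
global rotation is never removed): rotational/translational contamination sits
below ~100 cm⁻¹ where it is recognizable in the spectra, and for
fixed-boundary models the centre-of-mass motion is itself physical. The CLI
exposes `--remove-com` where solvated-molecule work wants it.

The paper-scale question of whether solvent coordinates should enter K is left
to the user: the CLI `--select` flag restricts the analysis to an atom subset
(1-based ranges), defaulting to all atoms in the file.

## Excited-state projection

Excited-state ensembles are projected with the **ground-state** L
(Q̇_ES = Lᵀ q̇_ES), the approximation being valid while the relaxation stays
near the Franck–Condon region; the package deliberately offers no re-derivation
of excited-state compositions. t = 0 is each member's first frame — the
excitation instant. Members are validated against the mode set's atom ordering
(first mismatching index reported) and truncated to a common window when
requested.

Ensemble averaging is performed on wavelet **power** maps by default. Member
trajectories have uncorrelated vibrational phases, so averaging raw velocities
cancels exactly the oscillations of interest; power averaging preserves
transient band intensity, which is how ensemble spectrograms are normally
built. The phase-sensitive alternative (`average_mode_velocities`) is provided
explicitly for coherent-ensemble studies.

## Morlet CWT

Mother wavelet: ψ(t) = π^(−1/4) e^(iω₀t) e^(−t²/2), **without** the
admissibility correction term, whose magnitude is < 1e−7 at the enforced
ω₀ ≥ 5; the default ω₀ = 6 is the standard time/frequency compromise for
spectrogram work. Scale maps to wavenumber by the centre-frequency convention
ν = ω₀/(2πa). The default grid is 150 logarithmic scales over 50–2000 cm⁻¹:
log spacing gives uniform relative resolution, and the lower bound avoids the
ν → 0 scale divergence while covering the low-frequency skeletal range of
interest.

The discretized transform W(a, b) = (1/√a)·Σ_t x(t)·ψ*((t−b)/a)·dt is
evaluated for all b at once by FFT over the signal zero-padded to the next
power of two at least twice its length, with the wavelet kernel sampled in the
time domain on the same padded grid — so the FFT path computes *exactly* the
same finite sum as the brute-force evaluator `cwt_direct`, and the two agree
to rounding (the suite's core anti-bug property). Padding values are zero;
edge-contaminated cells are flagged rather than trimmed.

Cone of influence: a cell at scale a is flagged when the e-folding distance
√2·a of the Gaussian envelope exceeds the distance to the nearer signal edge;
`coi[t]` stores the largest trustworthy row index per column (frequencies are
stored descending). Note that *at* the COI boundary the truncated Gaussian
tail still removes ½·erfc(1) ≈ 8% of the kernel amplitude (≈ 15% of power);
quantitative flatness/kinetics statements in the tests therefore use columns
at twice that distance, while the COI mask remains the conventional
edge-effect indicator.

Power maps carry arbitrary units. The library returns raw |W|² so that
linearity and amplitude-squared scaling hold on library objects; normalization
to the map maximum (the convention for plotting) is applied at the CLI/export
layer by default with `--no-normalize` to disable. Band kinetics are trapezoid
integrals of power over a frequency window; onset times are read as the
linearly interpolated half-rise to the late-time plateau.

## Synthetic ground truth

- **Harmonic models** are 1-D per atom (atoms on the x axis): the
  force-constant matrix is explicit, the mass-weighted eigenproblem is the
  analytic oracle, and trajectories are generated *analytically per mode* —
  each nonzero mode gets energy E ~ Exp(k_BT) (the classical Boltzmann
  distribution of a harmonic mode) and a uniform phase, then evolves as
  A·sin(ωt + φ). No integrator error enters oracle comparisons. A single
  realization's time-averaged kinetic energy is E/2, exponentially distributed
  around k_BT/2 — equipartition is an ensemble statement, and is tested as the
  mean over ~1000 seeded realizations.
- The **reference chain** (`default_chain`) is H–C–O–N–D between fixed walls
  with springs [0.03, 0.06, 0.10, 0.08, 0.05, 0.02] amu/fs², chosen once to
  give five well-separated modes at ≈ 147/459/725/1035/1619 cm⁻¹ — spanning
  the low-frequency region probed by transient Raman while keeping every mode
  nondegenerate so vector recovery is well-posed. Default sampling: 300 K,
  dt = 0.5 fs, 2¹⁵ frames (≈ 74 periods of the slowest mode).
- **Transient activation** (`sample_activation_trajectory`) holds one mode at
  rest until a switch time, then oscillates it with a chosen energy and seeded
  phase over thermal background in the other modes — the stand-in for a mode
  lighting up during excited-state relaxation. The acceptance workflow uses a
  5-member ensemble, 300 fs delay, activation energy 5 k_BT.
- The **Morse oscillator** (V = D(1−e^(−ax))², defaults D = 0.01 amu·Å²/fs²,
  a = 2 Å⁻¹, m = 1.008 amu → harmonic limit ≈ 1496 cm⁻¹) is propagated with
  velocity-Verlet, substepped so ω₀·h ≤ 1e−3: the symplectic error then stays
  below 1e−6 relative energy with no secular drift (numba-compiled loop with a
  pure-python fallback). Its exact classical frequency ω(E) = ω₀√(1 − E/D) is
  the red-shift oracle.
- **Switch signals** are phase-continuous two-frequency sinusoids with
  optional seeded Gaussian noise, used to validate time localization against a
  known switch time.

What the generators do *not* emulate: mode–mode anharmonic coupling, spectral
diffusion, solvent friction/dephasing, or any electronic-structure effect.
Passing tests demonstrate that the covariance/projection/wavelet machinery is
numerically correct and recovers known kinematics; they do not validate the
physical approximation that ground-state compositions persist in a real
excited state.

## Problem sizes and numerical choices

Analyses in the tests and the acceptance script use 2¹⁵-frame ground-state
trajectories, 4096-frame excited-state members and 120–150 scale CWTs — sizes
at which every stage completes in seconds on one core while leaving frequency
resolution (≈ 0.5 cm⁻¹ after padding) far below the 1% recovery tolerances.
Extended-XYZ output uses 17 significant digits so write→read round trips are
bit-exact. All generators are exactly reproducible from integer seeds.

## Known limitations

- Extended XYZ is the only trajectory format (a deliberate scope cut); use a
  converter for DCD/TRR/NetCDF. No periodic-boundary unwrapping.
- Velocity estimation from positions is central-difference only (endpoints
  dropped); accuracy degrades as (ω·dt)²/6 for fast modes.
- The CWT stores dense complex coefficient matrices; million-frame signals at
  hundreds of scales will be memory-hungry (use `keep_coefficients=False`).
- Mode identity across separate analyses is by eigenvalue order, which is not
  stable under resampling; match modes by vector overlap when comparing runs.
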