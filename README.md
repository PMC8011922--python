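# modewave

Time-resolved vibrational analysis of molecular-dynamics trajectories:
generalized vibrational modes from the velocity covariance matrix, and
time–frequency localization of their transient activity with a continuous
Morlet wavelet transform.

## Who this is for

Simulators of photoinduced processes (excited-state relaxation, proton
transfer, vibrational energy flow) who have equilibrium and excited-state MD
trajectories and want to know **which vibrations light up, when** — the
simulation-side counterpart of femtosecond stimulated Raman kinetics.

## The method

Let **q̇**(t) be the 3N vector of mass-weighted atomic velocities,
q̇<sub>3a+k</sub> = √m<sub>a</sub>·v<sub>a,k</sub>. From an equilibrium
trajectory the package builds the covariance matrix

&nbsp;&nbsp;&nbsp;&nbsp;K<sub>ij</sub> = ⟨q̇<sub>i</sub> q̇<sub>j</sub>⟩,

the time average of the raw velocity second moment. Diagonalizing K gives the
orthogonal matrix **L** whose columns are **generalized modes**: collective
coordinates with mutually uncorrelated velocities. No quadratic potential is
assumed, so the modes are defined at any temperature and carry intrinsically
anharmonic frequencies, assigned from the Fourier transform of each projected
velocity autocorrelation function.

For an ensemble of excited-state trajectories started from ground-state phase
space points, the ground-state composition is assumed to persist near the
Franck–Condon region, and mode velocities follow from the same transformation,
**Q̇**<sub>ES</sub>(t) = **L**ᵀ **q̇**<sub>ES</sub>(t). Each Q̇<sub>α</sub>(t)
is then decomposed over dilated/translated copies of the Morlet mother wavelet
ψ(t) = π<sup>−1/4</sup>e<sup>iω₀t</sup>e<sup>−t²/2</sup>,

&nbsp;&nbsp;&nbsp;&nbsp;W<sub>α</sub>(a, b) = a<sup>−1/2</sup> ∫ Q̇<sub>α</sub>(t) ψ*((t−b)/a) dt,

with scale a ∝ 1/ν and translation b. The power |W<sub>α</sub>(ν, t)|² is the
time-resolved vibrational spectrum of mode α; band integrals of the
ensemble-averaged power give rise/decay kinetics of individual vibrations.

Internal units are Å / fs / amu; frequencies are reported in cm⁻¹
(1 fs⁻¹ ≈ 33356.41 cm⁻¹).

## Worked example

A thermally sampled 5-atom harmonic chain (H–C–O–N–D between fixed walls,
2¹⁵ frames at dt = 0.5 fs) has five analytic normal modes. Recovering them
from the trajectory alone:

```python
import numpy as np
from modewave import (mass_weight, compute_covariance, diagonalize,
                      assign_frequencies)
from modewave.synthetic_data import (default_chain, sample_harmonic_trajectory,
                                     analytic_normal_modes)

model = default_chain(temperature=300.0, dt=0.5, n_frames=2**15, seed=1)
series = mass_weight(sample_harmonic_trajectory(model))
modes = assign_frequencies(diagonalize(compute_covariance(series)), series)

analytic, _ = analytic_normal_modes(model)
print("analytic (cm^-1):", np.round(analytic, 2))
print("recovered (cm^-1):",
      np.round(np.sort(modes.frequencies[~np.isnan(modes.frequencies)]), 2))
```

prints

```
analytic (cm^-1): [ 146.62  459.04  724.75 1034.5  1619.37]
recovered (cm^-1): [ 146.58  459.07  724.74 1034.18 1619.47]
```

— every mode frequency is recovered to well under 1%, and the corresponding
eigenvectors overlap the analytic normal modes with |dot| > 0.999. The ten
remaining modes (y/z motion of a 1-D model) have zero variance and an
undefined (NaN) frequency.

The same pipeline is available from the shell:

```sh
modewave synth chain --out chain.xyz --frames 4096 --seed 3
modewave modes   --traj chain.xyz --dt 0.5 --out gs/
modewave project --traj es1.xyz --traj es2.xyz --modes gs/modes.npz --out proj/
modewave wavelet --series proj/es1.modes.tsv --series proj/es2.modes.tsv --out wt/
```

`wavelet` writes one TSV spectrogram per mode (rows: cm⁻¹ descending, columns:
fs), ensemble-averaged over the input series, normalized to its maximum.

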