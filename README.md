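# dielax

Dielectric relaxation analysis of aqueous biomolecule solutions: decompose
complex permittivity spectra ε\*(ω) = ε′ − iε′′ into superposed Debye
processes, predict rotational-diffusion relaxation times of ellipsoidal
solutes from hydrodynamics, and estimate what a dilute rod-polymer
(collagen) network does — and does not — do to the solution's dielectric
response.

## The scientific problem

A few wt% of rod-like collagen (atelocollagen, ~1.5 nm × 300 nm, ~300 kDa)
turns water into a liquid hundreds of times more viscous, yet its
GHz-range dielectric spectrum is nearly indistinguishable from pure
water's. The way to probe the *local* viscosity — the friction a
molecule-sized object actually feels — is to dissolve a small solute
(an amino acid) and watch its rotational-diffusion relaxation. `dielax`
packages the complete analysis chain for this kind of study:

1. **Spectral decomposition.** Permittivity spectra are fitted with

   ε\*(ω) = ε∞ + Δε_L/(1+iωτ_L) + Δε_M/(1+iωτ_M) + Δε_H/(1+iωτ_H)
   [+ σ_dc/(iωε₀) in the loss],

   the L (low-frequency) process being solute rotation, H the bulk water,
   and M a small intermediate process. Fitting is joint over ε′ and ε′′,
   in log(τ), log(Δε) space with seeded multi-start (`lmfit`).

2. **Hydrodynamic prediction.** For a prolate solute with semi-axes
   a ≥ b, axial ratio ρ = b/a, and dipole along the long axis, Perrin's
   extension of the Stokes–Einstein–Debye law gives

   τ_rot = (8πηa³/3k_BT) · (1−ρ⁴) / [(2−ρ²)·L/√(1−ρ²) − 1],
   L = ln((1+√(1−ρ²))/ρ),

   and the measured dielectric time is τ_DR = 3ε_s/(2ε_s+ε∞) · τ_rot
   (macroscopic-field correction). The ratio τ_obs/τ_pred reads as
   η_local/η_water.

3. **Composition estimators.** Volume fraction per wt% of rods, the
   ideal-mixing decrement of the static dielectric constant, the bound-
   water mole fraction, and the number of rods per (rod-length)³ cube.

4. **Synthetic spectra.** A generator producing band-limited (0.5–25 GHz
   TDR, 0.3–2.5 THz THz-TDS) multi-Debye spectra with ±3% multiplicative
   noise and optional dc-conductivity contamination, for benchmarking the
   decomposition when raw measurements are unavailable.

## Worked example

Predict the rotational relaxation time of glycine (semi-axes 3.67 × 2.11 Å)
in water at 293 K and compare with the observed L-process time:

```python
import dielax as dx

geom    = dx.EllipsoidGeometry.from_angstrom(3.67, 2.11)
solvent = dx.SolventConditions(temperature=293.0, viscosity=1.002e-3)
context = dx.CorrectionContext(static_permittivity=120.0,
                               high_freq_permittivity=91.3)

tau_rot = dx.perrin_tau_rot(geom, solvent)          # 6.77e-11  (67.7 ps)
tau_a   = dx.predict_tau_a(geom, solvent, context)  # 7.36e-11  (74 ps)
ratio   = dx.local_viscosity_ratio(72e-12, tau_a)   # 0.98
```

The 67.7 ps microscopic time is lifted by the correction factor
3·120/(2·120+91.3) = 1.0866 to 74 ps; the observed 72 ps gives a
local-viscosity ratio of 0.98 — glycine feels pure-water friction.

Or from a shell, with the spectral decomposition in the loop:

```sh
dielax simulate --fixture glycine_solution --band tdr --noise 0 --out glycine.csv
dielax fit --input glycine.csv --processes 3 --out fit.json
# converged=True  tau_L=72.0 ps  tau_M=25.0 ps  tau_H=9.4 ps
dielax run --out results/study
```

which prints the full observed-vs-predicted table:

```
solute         tau_L obs (ps)  tau_a calc (ps)   ratio
glycine                    72               74    0.98
beta-alanine              107              108    0.99
L-serine                  123              115    1.07
L-arginine                309              282    1.10

collagen 4.0 wt%:
  volume fraction / wt%   0.01 (exact 0.0106)
  dielectric decrement    3.2
  bound water fraction    1.50%
  rods per (300 nm)^3     2000 (exact 2168)
```

Ratios near 1 for all four solutes, while the bulk viscosity of the same
solutions exceeds water's by two orders of magnitude: the collagen network
raises the macroscopic viscosity without touching the local one. The
mixture block shows why the network is dielectrically invisible — it
occupies ~4% of the volume and binds at most 1.5% of the water.

## The analysis, step by step

The numbered scripts under `analysis/` run the study as a narrative —
each writes its tables under `results/`:

| script | what it does |
|---|---|
| `01_simulate_spectra.py` | synthetic TDR spectra for water, glycine and collagen+glycine systems |
| `02_fit_spectra.py` | three-Debye decomposition of each spectrum |
| `03_recovery_benchmark.py` | 20-replicate Monte-Carlo: is τ_L measurable at 3% noise, and is it the same with and without collagen? |
| `04_predict_rotation_times.py` | Perrin predictions vs observed τ_L for the four amino acids |
| `05_mixture_estimates.py` | the four composition estimators at 4 wt% |
| `06_full_study.py` | everything in one `run_study` pass |

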