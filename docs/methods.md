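# Methods

## Dielectric model

The forward model is a sum of pure Debye terms over a high-frequency
baseline,

ε\*(ω) = ε∞ + Σ_k Δε_k/(1 + iωτ_k),  ε\* = ε′ − iε′′,  ω = 2πf,

with an optional ionic dc-conductivity contribution σ_dc/(ωε₀) added to
the loss channel only (no electrode-polarization model). Each Debye term
is Kramers–Kronig consistent by construction: its loss peaks exactly at
f = 1/(2πτ) with height Δε/2, ε′ is monotone non-increasing in frequency,
and the zero-frequency limit of ε′ is the static permittivity
ε_s = ε∞ + ΣΔε. Frequencies are Hz at every interface (ω is formed
internally); the loss is stored as a positive magnitude and the complex
value ε′ − iε′′ assembled on demand. A per-process Cole–Cole exponent α
(term Δε/(1+(iωτ)^{1−α})) is available to explore whether a small
intermediate process can be absorbed into a symmetrically broadened
low-frequency process; it is not used by any default path.

Physical constants are fixed at CODATA/SI values to 9 significant digits
(`dielax.constants`): ε₀ = 8.85418781e-12 F/m, k_B = 1.38064900e-23 J/K,
N_A = 6.02214076e23 /mol.

## Spectral decomposition

`fit_relaxation` minimizes the joint residual over both channels
simultaneously with `lmfit` (trust-region least squares). Numerical
choices:

- **Parameterization.** τ and Δε are optimized as log10 values, which
  enforces positivity structurally (no clipping) and conditions the
  problem across the several decades the parameters span. Default τ
  bounds extend 1.5 decades beyond the band-implied interval
  [1/(2πf_max), 1/(2πf_min)]; ε∞ is bounded below by 1.
- **Weighting.** Default `relative` mode divides each residual by the
  channel's data magnitude floored at 1 — ε′ and ε′′ differ by up to two
  orders of magnitude across the band, and the measurement accuracy these
  data carry is a uniform relative figure (~±3%). `uniform` weighting is
  available.
- **Initialization.** τ seeds log-spaced across the band-implied
  interval, Δε seeds splitting the observed ε′ span equally, ε∞ seeded
  from the highest-frequency ε′. A spectrum with no ε′ dispersion is
  rejected as degenerate rather than seeded with zero strengths.
- **Multi-start.** 5 restarts (seeded PCG64; log-normal perturbations of
  0.3 decades in τ, 0.2 in Δε) guard against local minima; the lowest
  joint cost wins. Convergence tolerances default to 1e-12; failure to
  converge is flagged in the report, never silently returned.
- **Labelling.** After fitting, processes are relabelled by descending τ:
  L/M/H for three processes, L/H for two, a single L otherwise.
- **dc conductivity.** Off by default. `"auto"` fits once without a dc
  term, and refits with one only if the mean relative excess loss over the
  3 lowest-frequency points exceeds 5% and the penalized criterion
  improves — low-frequency excess loss is the signature of ionic
  contamination, but a dc term should not be paid for on clean data.
- **Model ranking.** `compare_models` uses an AIC-like criterion
  N·ln(χ²/N) + 2k on a fixed relative weighting, with the per-point χ²
  floored at (1e-8)²: residuals at optimizer round-off are treated as
  exact so that two numerically perfect fits rank by parameter count
  (parsimony) instead of by meaningless sub-machine differences.
- **Standard errors** come from the local curvature (covariance) and are
  mapped out of log space as s(τ) ≈ τ·ln10·s(log₁₀τ); an indefinite
  covariance (degenerate fit) yields NaN errors, not a crash.

Each spectrum is fitted independently on whatever grid it carries; TDR
and THz segments can be fitted jointly by concatenating grids, but no
cross-sample coupling is attempted.

## Hydrodynamic prediction

For a prolate ellipsoid with SEMI-axes a ≥ b (Å accepted at the
interface, SI internally), axial ratio ρ = b/a, dipole parallel to the
long axis:

τ_rot = (8πηa³/3k_BT) · (1−ρ⁴) / [(2−ρ²)·L/√(1−ρ²) − 1],
L = ln((1+√(1−ρ²))/ρ).

For |1−ρ| < 1e-9 the analytic sphere limit 4πηr³/(k_BT) is dispatched to
avoid 0/0; the prolate expression is numerically stable down to that
threshold (relative error < 2e-6 at ρ = 1−1e-6). The measured dielectric
time is τ_DR = 3ε_s/(2ε_s+ε∞)·τ_rot, a factor confined to [1, 1.5); for
a solute L process, ε∞ here is the L-process high-frequency limit (the
permittivity remaining once the L process has relaxed), not the full-band
ε∞. The prediction uses the bare molecular geometry — no hydration
shell — because the volume of the hydration layer is not well defined;
the two largest solutes (L-serine, L-arginine) consequently come out
~7–10% below observation, consistent with extra hydrated volume. All
internal arithmetic is double precision; rounding to integer picoseconds
happens only at report time. Default solvent: water at 293 K,
η = 1.002 mPa·s (literature value). Whether 293 or 293.15 K is used
shifts the predictions by well under 1 ps.

## Composition estimators

Four linear/power-law estimators under a dilute-aqueous assumption
(solution density 1 g/cm³, configurable):

- φ per wt% = (0.01·ρ_solution/M)·N_A·πr²ℓ — 0.0106 for the default rod
  (1.5 nm × 300 nm, 300 kg/mol), i.e. 0.01 to one significant figure.
- Δε = wt% · (φ/wt%) · ε_water, ideal volume-exclusion mixing with
  ε_water(293 K) = 80.2 by default: 3.2 at 4 wt% (using the one-figure φ).
- Bound-water mole fraction = (waters/residue · residues · n_rod)/n_water
  per unit solution mass; 1.5% at 4 wt% with 3000 residues and 2 waters
  per residue. The 2 waters/residue is the upper end of the "one or
  several" range reported for triple-helix hydration, hence "at maximum".
- Rod count = (wt·ρ/M)·N_A·side³: 2168 (≈2000) in a (300 nm)³ cube at
  4 wt%.

Exact values are always returned; report mode rounds to one significant
figure, the precision at which such plausibility estimates are quoted.

## Synthetic data

Grids are log-spaced with ceil(points/decade × decades)+1 points,
endpoints included; default bands are TDR 0.5–25 GHz and THz-TDS
0.3–2.5 THz at 20 points/decade. Noise is multiplicative Gaussian,
1 + N(0, σ_rel) per channel, i.i.d. across frequencies and independent
between channels by default, with the loss truncated at zero; σ_rel
defaults to 0.03, the stated accuracy of TDR permittivity measurements.
This emulates the *net* amplitude uncertainty only — real TDR timing
jitter and THz optical-path errors are frequency-correlated in ways not
modelled here, so recovery benchmarks bound what white relative noise
implies, not every instrumental systematic. The PRNG is
`numpy.random.Generator(PCG64)`, seeded explicitly everywhere.

Fixture models: the glycine-solution L process (Δε = 28.7, τ = 72 ps,
ε_s = 120, L-process limit 91.3) reflects the measured system; the pure-
water constants (ε_s 80.2, τ 9.4 ps, ε∞ 5.3) are literature-style values;
the M process (Δε = 3, τ = 25 ps) and the split of the remaining strength
between ε∞ (5.0) and the H process are invented stand-ins — no measured
values exist for them, and no downstream result depends on their specific
magnitudes. The collagen+glycine fixture shares the L and M processes
exactly and carries the 4 wt% volume-exclusion decrement on the water
strength, encoding the finding it is used to re-enact: solute rotation is
insensitive to the collagen network.

## Benchmark problem sizes

The recovery benchmark fits 20 noisy replicates per system on the
35-point TDR grid — enough for a stable median and a meaningful rank test
while each fit (5 starts) stays under a second. The noise-bias check uses
1000 replicates of the forward model only (no fitting).

## Known limitations

- Only pure-Debye (plus optional Cole–Cole) terms; no Havriliak–Negami or
  stretched-exponential shapes, no temperature dependence of parameters.
- Prolate, dipole-parallel geometry only; no oblate or perpendicular
  variants, no translational diffusion, no axis estimation from
  structures (axes are inputs).
- Conversion of instrument-native records (TDR waveforms, THz time
  traces) to permittivity is out of scope; inputs are already-reduced
  spectra.
- The composition estimators are deliberate order-of-magnitude tools; no
  percolation or network-topology modelling stands behind the rod count.
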