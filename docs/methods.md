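# Methods

This note documents the models implemented in `nucbind`, their
assumptions, the numerical choices, and what the synthetic-data
generators do and do not emulate.

## Equilibrium models

**1:1 binding with depletion.** The complex concentration solves
[PL]² − (P0 + L0 + K_D)[PL] + P0·L0 = 0. The smaller root is evaluated
in the product/sum form 2·P0·L0 / (b + √(b² − 4·P0·L0)) with
b = P0 + L0 + K_D, which is numerically stable in the stoichiometric
limit K_D ≪ max(P0, L0) where the textbook (b − √disc)/2 form suffers
catastrophic cancellation. All concentrations are carried in mol/L
internally; unit conversion (mM, μM, pmol in a load volume) happens only
in `nucbind.units` at the I/O boundary, because silent unit errors are
the dominant failure mode in affinity work.

**Two equivalent sites.** A nucleosome presents two symmetric H3 tails,
so a reader binds with 2:1 stoichiometry. The two sites are modelled as
equivalent and *independent*: the free ligand x solves
x + 2·N0·x/(K_D + x) = L0 (again the stable quadratic root), the
per-site occupancy is θ = x/(K_D + x), and the 0/1/2-bound species are
binomial, ((1−θ)², 2θ(1−θ), θ²). Independence is the simplest model
consistent with both the gel-shift and the line-shape data; there is no
evidence for cooperativity between the two tail sites, and we
deliberately do not add an interaction parameter (no Hill coefficient,
no anti-cooperativity) without data to constrain it.

**Avidity.** For bipartite binding the enhancement is expressed as an
effective concentration C_eff = (K_D,tail × K_D,DNA)/K_D,nucleosome,
with units mol/L; the fold enhancement is the plain ratio of a reference
K_D to the complex K_D, also reported rounded to the nearest power of
ten; the complex lifetime is 1/k_off.

## CSP isotherm fit

Combined CSPs use Δδ = √(Δδ_H² + (w·Δδ_X)²) with the conventional amide
weight w = 0.2 for ¹⁵N (0.3 for ¹³C methyls); the weight is configurable
since the literature is not uniform. Significance thresholds are the
trimmed mean plus n·σ (defaults: 10% trimmed per tail, n = 2); σ is the
sample standard deviation of the trimmed set by default, with the
full-set σ available, since conventions differ.

The fit assumes fast exchange: each residue's CSP is proportional to the
receptor bound fraction, csp_r(i) = csp_max,r · [PL]_i/P0. The
depletion-corrected quadratic is always used even when ligand excess
would justify the hyperbolic approximation — one code path, no regime
bugs. All residues are fitted *globally* with one shared K_D: in the
weak-binding regime single curves are nearly straight lines and only the
ensemble curvature identifies K_D.

The problem is separable: at fixed K_D the amplitudes csp_max,r are
linear least squares (variable projection), so the K_D profile is
computed exactly on a log-spaced multi-start grid (1e-8–1e2 M, 61
points), minimised by bounded scalar search, and polished by
Levenberg–Marquardt over (log10 K_D, amplitudes). LM converges
quadratically on near-zero-residual problems, which is what makes the
σ = 0 round trips recover truth to ~machine precision.

95% confidence intervals are profile likelihood: bounds where
RSS(K_D) = RSS_min·(1 + F(0.95; 1, n−p)/(n−p)), located by stepping
0.25 decades and refining with Brent's method. A titration that never
saturates has an open upper bound, reported as +inf with a warning —
not silently truncated to the search bound.

`truncate_series` restricts curves to points with ligand ≤ a cutoff
(the free point always survives), reproducing the practice of fitting a
weak binder only over the titration interval where the dilution series
is reliable; refitting truncated noiseless data returns the same K_D.

## Exchange line-shape fit

The observed spin is a methyl group on the H3 tail (V35 in the
motivating system). Each tail site is either free or reader-bound, so a
**two-state** exchange matrix suffices; the 1:2 (nucleosome:reader)
stoichiometry is honoured through the mass balance that sets the
populations, not by enlarging the state space. A hypothetical third
state (reader bound to DNA only, with the tail free) cannot be
distinguished from the free state by the tail methyl and is not
modelled; this is an explicit assumption.

Transverse magnetization evolves under
L = diag(iΩ_j − R2_j) + K, where K = [[−k_fb, k_bf], [k_fb, −k_bf]] has
zero column sums (population conservation by construction). At each
titration point the two-site mass balance gives the free ligand x and
occupancy θ; then k_bf = k_off and k_fb = k_off·x/K_D, whose implied
equilibrium bound population x/(K_D + x) equals θ exactly. The FID is
1ᵀ·expm(L·t)·M0 with M0 = (1−θ, θ), propagated by eigendecomposition of
the constant 2×2 matrix — exact, with no step-size error; a positive
real eigenvalue (unphysical R2/rates) raises immediately.

Spectra are produced by exponential apodization, halving of the first
FID point (the trapezoidal correction that makes the discrete transform
match the continuous one to O(Δt²)), zero filling ×2, and FFT; the
normalisation makes the integral over the frequency axis in Hz equal to
the t = 0 magnetization. The test suite verifies the whole path against
an independently coded closed-form frequency-domain solution (analytic
2×2 inverse) to < 0.1% RMS across slow, intermediate and fast regimes,
and checks integral conservation, coalescence behaviour, the Lorentzian
width identity FWHM = R2/π, and the fast-exchange averaging limit.

The trace axis is ¹³C by default, at a 900 MHz ¹H field; the ¹³C observe
frequency is taken as 226.19 MHz (the constant only sets the ppm↔Hz
scale of Δω and is configurable, as is a ¹H axis). Defaults for the
quantities that are not printed in the source experiments — Δω =
0.35 ppm, R2_free = 8 s⁻¹, R2_bound = 40 s⁻¹, sweep 6 ppm, 1024 points —
were chosen once to reproduce the qualitative appearance of the
experimental titration (sharp mobile-tail resonance, strongly broadened
bound state) and are documented generator assumptions, not measured
values.

Fitting minimises χ² = Σ_traces Σ_points (obs − s_t·sim)² jointly over
(log10 K_D, log10 k_off, Δω, R2_free, R2_bound, free-state offset), with
the per-trace scales s_t solved analytically at every evaluation. Nine
coarse (K_D, k_off) starting points are ranked by one χ² evaluation and
the best two are refined by bounded least squares. 95% intervals come
from the likelihood-ratio profile over log10 K_D and log10 k_off
(minimising over the other rate parameter; the shape parameters are held
at the best fit and the scales re-solved — full re-optimisation at every
profile point changes the intervals negligibly and would dominate the
cost of the replicate studies). A profile that never crosses the
threshold within ±2 decades is reported open on that side with a flag —
this is how a near-stoichiometric titration correctly yields only an
upper bound on K_D ("95% probability K_D < x"). A posterior-sampling
alternative (emcee, flat priors in the log parameters) is available
behind the same interface and agrees with the profile intervals on test
data.

## EMSA fit

Band densities are converted to species fractions by per-lane
normalisation, which removes lane-loading differences as nuisance
parameters; this assumes equal detection response per nucleosome across
the free/+1/+2 bands (ethidium stains the same wrapped DNA in every
species). An optional per-band response vector relaxes the assumption.
The fit minimises the squared deviation between observed and binomial
model fractions over all lanes with the microscopic K_D as the single
parameter (log-grid + scalar minimisation + LM polish), with
profile-likelihood 95% intervals. Fitting fractions rather than raw
densities is a deliberate choice: raw densities would require one free
loading scale per lane and add nothing. A titration whose largest
ligand dose is below 0.5 equivalents is rejected as unable to constrain
K_D. Gel loads are specified as pmol in a load volume (1.5 pmol/8 μL =
0.1875 μM, 3 pmol/8 μL = 0.375 μM — the two standard presets).

## Synthetic-data generators

The generators define the study conditions used throughout the tests and
the reproduction script:

| preset | receptor | schedule | truth | noise |
|---|---|---|---|---|
| csp_peptide | 0.3 mM | 0, 0.5, 1, 2, 4, 8, 16, 30 mM | K_D 17 mM | σ 0.004 ppm |
| csp_dna | 0.3 mM | 0, 0.05, 0.1, 0.2, 0.4, 0.8, 1.2 mM | K_D 150 μM | σ 0.004 ppm |
| csp_mla | 0.3 mM | 0, 0.25, 0.5, 1, 2, 4 mM | K_D 11 mM | σ 0.003 ppm |
| lineshape_nucleosome | 116 μM | ratios 0, 0.5, 1, 1.8, 2.7 | K_D 1.5 μM, k_off 500 s⁻¹ | 2% peak height |
| emsa | 0.375 μM | equivalents 0, 0.5, 1, 2, 3 | K_D 0.5 μM | 5% fraction, 10% lane loading |

The EMSA equivalents schedule follows the published gel design; the NMR
schedules are assumptions (the published experiments state stock
concentrations and endpoints — peptide stock 110 mM, DNA stock 11.5 mM,
final nucleosome ratio 1:2.7 — but not the intermediate points), chosen
as geometric-ish series a spectroscopist would run. The per-residue
saturation CSPs (0.08–0.30 ppm over six reporters) represent a shallow
binding surface with a handful of strongly and weakly perturbed amides.

Noise models: CSP curves receive Gaussian noise on the combined CSP,
folded at zero, because a measured CSP is a vector magnitude and can
never be negative (this makes near-zero points Rician-like, as in real
data); peak-list mode instead perturbs the raw ¹H/X shifts (σ/√2 and
σ/(√2·w)) so the derived combined CSP has spread ≈ σ, with the clean
perturbation split between ¹H and X at a fixed 35° direction. Line-shape
noise is additive Gaussian with σ equal to the stated fraction of each
trace's peak height. EMSA fractions are perturbed by zero-truncated
Gaussian noise and rescaled by a log-normal per-lane loading factor.
One RNG stream per dataset; identical (spec, seed) pairs are
byte-identical on disk, and the seed is recorded in every output header.

What the generators do **not** emulate: peak overlap and tracking
ambiguity in crowded spectra, baseline and phase errors in 1D traces,
scalar-coupling multiplet structure, smeared or intermediate gel bands,
and any systematic (non-random) densitometry error. Passing recovery
tests therefore demonstrates correctness and statistical calibration of
the fitters under the assumed noise structure, not robustness to those
real-data artefacts.

## Reproduction studies and problem sizes

`scripts/acceptance.py` runs 100 CSP replicates (truncated MLA-peptide
design), 50 line-shape replicates, and 100 EMSA replicates, with
replicate seeds drawn from the user seed, and reports median recovered
constants. These sizes give medians stable to a few percent across run
seeds while completing in well under a minute on one CPU; the same
replicate counts are used by the acceptance tests. The three printed
arithmetic identities (effective concentration 1.7 M, lifetime 2 ms,
~10⁴-fold enhancement) are recomputed exactly from their inputs in the
test suite.

## Known limitations

* No cooperative or >2-site binding models; no kinetic (pre-equilibrium)
  titrations.
* Line shapes are strictly two-state, 1D, single-quantum; no full 2D
  methyl-TROSY simulation, no relaxation dispersion.
* The CSP fitter assumes fast exchange throughout; intermediate-exchange
  CSP curvature ("peak walking" with broadening) is outside its model.
* Profile intervals assume approximately Gaussian residuals; for heavy
  noise the emcee interval method is preferable.
* EMSA densitometry itself (image → band densities) is out of scope.
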