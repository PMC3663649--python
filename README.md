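# nucbind

Quantitative analysis of multivalent nucleosome binding from solution NMR
and gel-shift data.

Reader domains such as the PSIP1 (LEDGF/p75) PWWP domain recognise
H3K36-methylated nucleosomes through two weak, adjacent interactions — an
aromatic cage engaging the methylated lysine of the H3 tail, and a basic
surface engaging the nucleosomal DNA. Neither contact alone binds tightly
(K_D in the mM range for the methylated peptide, ~10² μM for free DNA),
yet the assembled nucleosome is bound with low-μM affinity: linking the
two epitopes on one particle produces a large avidity gain. `nucbind`
implements the computations that quantify this bipartite recognition:

* **CSP isotherm fitting** — combined chemical shift perturbations
  Δδ = √(Δδ_H² + (w·Δδ_X)²) from Sparky-style peak lists, a
  trimmed-mean + 2σ significance threshold, and a *global* fit of the
  depletion-corrected 1:1 fast-exchange isotherm
  (one shared K_D, one Δδ_max per residue, profile-likelihood 95% CIs).
* **Exchange line-shape fitting** — 1D NMR line shapes under two-state
  chemical exchange by explicit evaluation of the 2×2 Bloch–McConnell
  matrix and calculation of the FID, with populations and
  pseudo-first-order rates tied to the 1:2 (nucleosome:reader) mass
  balance of the two equivalent H3-tail sites; joint fitting of
  (K_D, k_off, Δω, R2) across a titration, likelihood-ratio or
  posterior-sampling intervals.
* **EMSA densitometry fitting** — free/+1/+2 band densities converted to
  species fractions and fitted to the binomial 2:1 binding model for the
  microscopic K_D.
* **Avidity arithmetic** — the effective concentration
  C_eff = (K_D,tail × K_D,DNA)/K_D,nucleosome, fold enhancement, and
  complex lifetime 1/k_off.
* **Synthetic data generators** — seeded emulations of all three
  titration experiments at the study conditions, used by the test suite
  and the reproduction script.

The fitting stages are statsmodels-style model objects
(`CspTitrationModel`, `ExchangeLineshapeModel`, `EmsaModel`); each
`fit()` returns a results object carrying estimates, intervals,
diagnostics, `summary()` and `plot()`.

## Worked example

Avidity arithmetic from the three measured affinities
(tail 17 mM, DNA 150 μM, nucleosome 1.5 μM; k_off 500 s⁻¹):

```
$ nucbind avidity --kd-tail 17 --tail-unit mM --kd-dna 150 --dna-unit uM \
    --kd-complex 1.5 --complex-unit uM --koff 500
effective concentration : 1.7 M
fold enhancement        : 1.133e+04 (~10000-fold)
complex lifetime        : 2 ms
```

The effective concentration of 1.7 M means that once one epitope is
engaged, the second is presented to its binding surface at an apparent
local concentration of 1.7 mol/L — far above its own K_D, so the second
contact is essentially always made; the ~10⁴-fold enhancement over the
isolated peptide follows.

Simulate a methyl line-shape titration (116 μM nucleosome, reader added
to 2.7 molar equivalents, K_D 1.5 μM, k_off 500 s⁻¹, 2% peak-height
noise) and fit it back:

```
$ nucbind simulate --preset lineshape_nucleosome --seed 11 --out-dir demo_ls
$ nucbind fit-lineshape --manifest demo_ls/manifest.tsv --report demo_ls/fit.json
Two-state exchange line-shape fit (1:2 receptor:ligand mass balance)
====================================================================
K_D          : 1.54 uM   95%: [1.41, 1.68] uM
k_off        : 502 1/s  95%: [479, 527] 1/s
lifetime     : 1.99 ms
delta_omega  : 0.3505 ppm
R2 free/bound: 8.38 / 40 1/s
chi2         : 0.0559588
```

The fitted K_D and k_off recover the generator truth within the noise;
`delta_omega` is the free→bound ¹³C shift of the observed methyl group
and the R2 pair shows the line broadening of the tail upon binding.

The same works for `--preset csp_peptide | csp_dna | csp_mla` with
`fit-csp` (optionally `--max-ligand 4 --ligand-unit mM` to restrict the
fitted interval) and for `--preset emsa` with `fit-emsa`. Every report
is JSON with estimates, intervals, flags and input digests.

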