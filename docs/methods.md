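# Methods

## Model structure and assumptions

Both models describe a closed in vitro system: a well of culture medium
containing zoledronic acid (ZA) at concentration `Y` (μM) over a monolayer
of tumour cells with intracellular ZA `Z` and IPP `G` (both pmol per mg of
cellular protein).  The ZA kinetics are linear first-order exchange between
medium and cells with optional degradation on either side:

    dY/dt = −(kZY + kXY)·Y + (kYZ/ρZY)·Z
    dZ/dt = ρZY·kZY·Y − (kXZ + kYZ)·Z

`ρZY` (pmol/mgprot per μM) converts medium concentration to the
intracellular scale.  The cell→medium back-transfer therefore divides by
`ρZY`: this is the only dimensionally consistent form (the forward flux
multiplies by it), and the package's unit-rescaling property test pins it —
changing the intracellular unit by a factor c while scaling `ρZY`, `Z`, `G`
and `1/λGZ` accordingly must leave `dY/dt` invariant.

IPP is produced at a constant rate `kG` and eliminated at a rate ZA
suppresses.  Model 1 makes the suppression a direct exponential in `Z`;
Model 2 routes it through FPPS occupancy, with bound-enzyme percentage `B`
formed at a second-order rate `kBUZ·Z·U` and dissociating at
`kUBG·e^(−λUBG·G)` (accumulated IPP stabilises the inhibited complex).
The algebraic unbound fraction `U = 100 − B` is substituted directly, so
Model 2 is integrated as plain ODEs — the algebraic equation is explicit
and substitution is exact, which keeps the integrator simple and
bit-reproducible.  Enzyme conservation `U + B = 100` is consequently exact
at every step, and the suite asserts equality, not closeness.

In both models `kG = kXGtot·G0` is **derived** from the initial steady
state (no drug, antigen in equilibrium), never estimated: this encodes the
assumption that untreated cells sit at their IPP set point `G0` and removes
one degree of freedom from every fit.

Key assumptions inherited from this construction: production is constant
over 48 h (no feedback from the mevalonate pathway); no cell growth or
death; no ApppI/ApppD conjugation of the accumulated IPP; a single
homogeneous cell population.

## Parameters and scenarios

Four TOML scenarios (`model{1,2}_{continuous,pulse}`) encode the published
point estimates.  Representative values, continuous protocol: `kZY` 0.007/h
(uptake), `kXY` 0.004/h (medium degradation), `kYZ` 0.001/h (efflux),
`ρZY` 25.46, `kXZ` 0 (no intracellular degradation — the data support
none); Model 1 antigen block `kXG` 0.101/h, `kXGZ` 13.25/h, `λGZ` 0.195 per
pmol/mgprot, `G0` 12.71.  The pulse estimates differ sharply (`kZY` 0.607,
`kYZ` 18.06/h): the source analysis itself calls the pulse efflux rate
unlikely, and the scenarios reproduce it as printed without
reinterpretation.  Where the abstract-level value `kXGtot = 13.24/h`
disagrees with the internally consistent table value (0.101 + 13.25 =
13.35), the scenarios use the consistent one.

Dosing designs: continuous exposure at `Y0 = 25 μM`; pulse exposure with
washout at `t* = 1 h` realised as an instantaneous reset of `Y` to `Y*+`
(0 in the published fits) with intracellular states continuous across the
jump.  Sampling grids: {1,3,6,12,18,24,48} h (continuous), {0,1,3,6,12,18,
24,48} h and {0,4,8,12,24,42} h (pulse, the two source cell lines).

## Numerical choices

* **Integrator**: classic fixed-step RK4, default `h = 0.01 h`, with
  sample/washout times forced onto the grid (final partial step shortened),
  so reported values involve no interpolation.  Against the exact
  matrix-exponential solution of the linear (Y, Z) subsystem the default
  step is accurate to better than 1e−6 relative over 48 h across random
  parameter draws.  Halving the step changes continuous-scenario outputs by
  <1e−7 relative; under the pulse parameterization the fast pre-washout
  transient (`kYZ` = 18.06/h, `h·λ` ≈ 0.18) raises that to ~4e−6, still far
  below measurement noise.
* **Negativity guard**: round-off undershoots in (−1e−12, 0) are clipped to
  zero; anything more negative raises an integration error rather than
  being masked.
* **Search transform**: strictly positive parameters are optimised on the
  log scale; parameters starting at zero through an inverse soft-plus with
  a 1e−8 floor.  Non-negativity is thus structural, matching the practice
  of fixing parameters estimated at zero instead of letting the simplex
  cross zero.
* **Simplex controls**: total evaluation budget 5000·q split across 3
  restarts from the best point; `xatol` 1e−10 on the transformed scale
  (≈ relative), `fatol` 1e−8 **absolute** — scipy's Nelder–Mead has no
  relative loss tolerance, and an absolute threshold below the float64
  eps-floor of the loss magnitude would make convergence unreportable.
  Failed simulations during the search return a 1e12 penalty so the
  simplex can retreat.
* **Loss**: the default is the literal unweighted sum of squares over the
  stacked (Z, G) residuals.  Because G (~10³ pmol/mgprot under continuous
  dosing) dwarfs Z (~10²), an optional per-variable normalisation divides
  each variable's residuals by its observation SD; recovery experiments use
  it, otherwise the ZA-kinetic parameters are effectively unconstrained by
  the loss.
* **Covariance**: `V = s²(JᵀJ)⁻¹` with J the central-finite-difference
  Jacobian of the **unweighted** residual vector (relative step 1e−6, floor
  1e−8, one halving retry) and `s²` recomputed from that same unweighted
  vector — so the report is internally consistent even when the fit
  minimised the normalized loss.  N counts every non-missing scalar (Z and
  G separately); q counts free parameters.  Confidence limits use the
  normal multiplier 1.96, which reproduces the published table arithmetic
  exactly where a t-quantile does not.  Pairs with |correlation| > 0.99
  (configurable) are flagged as practically non-separable.

## Synthetic data: what it does and does not emulate

The generator simulates the true trajectory for a scenario, samples it on a
published grid and adds i.i.d. Gaussian noise per variable — the exact
error model the estimator assumes.  Default σ is 2 % of each variable's
sampled-trajectory maximum (a single pooled σ, available via
`homoscedastic=True`, drowns the smaller-scale variable).  Negative draws
are truncated to zero and counted.  Two consequences of the real study
geometry are worth knowing:

* Early-time values sit close to zero relative to σ (`G(1 h)` ≈ 26
  pmol/mgprot against σ_G ≈ 33 under continuous dosing; `Z(0) = 0` on the
  pulse grids), so truncation is *not* a per-seed rarity: it touches ~2 %
  of scalar observations, always at points whose true value is below ~4σ.
  The tests bound the truncated fraction and verify unbiasedness of the
  noise at all points ≥4σ.
* The generator produces one coherent dataset per scenario.  It does not
  emulate digitisation error from the source figures, detection limits of
  the HPLC-ESI-MS assay, or the source's pooling of two cell lines with
  ~100-fold different IPP magnitudes into one pulse fit.  Passing recovery
  tests therefore demonstrate estimator correctness under the assumed error
  model, not robustness to those real-data features.

## Recovery experiments and the identifiability asymmetry

With the medium concentration `Y` unobserved, the triple (`kZY`, `kXY`,
`ρZY`) contains a structurally flat direction: the product `ρZY·kZY` and
the total medium decay `kZY + kXY` are what the Z data see.  A noiseless
refit with `kXY` free drives the loss to ~1e−13 while leaving `kZY` several
percent off — which is precisely why `kXY` is excluded from the
identifiability analysis as highly correlated with the (`kZY`, `ρZY`)
couple, and why the package's correlation flag fires on exactly that
triple.  The noiseless recovery test therefore fixes `kXY`; with it held,
recovery from a 1.2×-perturbed start is exact to <1e−4 relative.

The noisy recovery experiment (30 seeded datasets, default noise,
normalized loss, free set {`kZY`, `ρZY`, `kXGZ`, `λGZ`} mirroring the
screening above) runs on the **pulse** scenario, whose washout transient
excites the ZA kinetics strongly.  There the ZA-kinetic parameters recover
with strictly smaller median relative error (~0.18–0.22) than the antigen
suppression constant `λGZ` (~0.24), reproducing the qualitative conclusion
that the antigen sub-model is the poorly identifiable part.  Under
*continuous* dosing the ordering inverts: the abundant, clean G data pin
the antigen parameters while the ZA pair wanders its sloppy valley — a
genuine property of the design, visible in the asymptotic CVs, and the
reason the asymmetry experiment is defined on the pulse protocol.  In the
continuous Model 2 scenario, `kUBG` and `λUBG` have exactly zero
sensitivity (the dissociation term is suppressed by `e^(−λUBG·G)` ≈ e^−49
throughout), so they are never freed in recovery experiments; JᵀJ would be
singular.

## Problem sizes

The test suite fits at RK4 step 0.02 h (indistinguishable from 0.01 at the
noise level, twice as fast) on the published 6–8-point grids; the oracle
and convergence checks use 100 random parameter draws; the Monte-Carlo
noise checks use 500 replicates; the asymmetry experiment 30 seeds.  All
sizes are fixed in the tests and chosen so each experiment's conclusion is
stable under reruns with different seed offsets.

## Known limitations

* The pulse ZA fit cannot capture the sub-hour uptake peak reported in the
  source data; no endocytosis delay compartment is modelled.
* No structural identifiability analysis (symbolic) and no
  profile-likelihood or bootstrap intervals — uncertainty is purely the
  local asymptotic covariance, which the flat directions above can make
  optimistic or singular.
* Metabolite conjugation (ApppI/ApppD), FPPS conformational sub-states,
  cytotoxicity and proliferation are out of scope.
* The published identifiability table's `λGZ` and `kBUZ` rows are not
  reproducible from the printed point estimates; the package reports what
  it computes and does not force agreement for those rows.
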