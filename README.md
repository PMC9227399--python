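# zaipp

Kinetic modelling of **zoledronic acid (ZA) cellular uptake** and the
resulting **isopentenyl pyrophosphate (IPP) accumulation** in tumour cell
cultures — simulation, ordinary-least-squares fitting, and practical
identifiability analysis.

ZA, a nitrogen-bisphosphonate, enters tumour cells from the culture medium
and inhibits farnesyl pyrophosphate synthase (FPPS), causing the mevalonate
intermediate IPP to accumulate.  IPP is the phosphoantigen that activates
Vγ9Vδ2 T cells, so predicting *how much IPP a given ZA exposure produces,
and when* matters for the design of γδ T-cell-based immunotherapy
protocols.  This package is aimed at modellers and experimentalists who
want to simulate those in vitro dosing experiments, refit the models to
their own time-course data, or probe which parameters such data can
actually constrain.

## The models

State variables: `Y` (μM) medium ZA, `Z` (pmol/mgprot) intracellular ZA,
`G` (pmol/mgprot) intracellular IPP, and for Model 2 the bound/unbound FPPS
percentages `B` and `U = 100 − B`.

Shared ZA kinetics (linear two-compartment exchange):

    dY/dt = −(kZY + kXY)·Y + (kYZ/ρZY)·Z
    dZ/dt = ρZY·kZY·Y − (kXZ + kYZ)·Z

**Model 1** suppresses IPP elimination phenomenologically with intracellular ZA:

    dG/dt = kG − [kXG + kXGZ·e^(−λGZ·Z)]·G

**Model 2** tracks enzyme occupancy explicitly:

    dB/dt = kBUZ·Z·U − kUBG·e^(−λUBG·G)·B,   U = 100 − B
    dG/dt = kG − (kXGU·U + kXG)·G

In both, the production rate is tied to an initial steady state,
`kG = kXGtot·G0` with `kXGtot = kXG + kXGZ` (Model 1) or
`kXGU·100 + kXG` (Model 2) — `kG` is derived, never fitted.

Two dosing protocols are supported: **continuous** exposure at 25 μM, and a
**pulse** — 1 h exposure followed by medium replacement, realised as an
instantaneous jump of `Y` to the post-washout residue `Y*+`.  Integration
is classic fixed-step RK4 (default 0.01 h) with the washout forced onto the
grid; the linear (Y, Z) subsystem has an exact matrix-exponential solution
used as an internal cross-check.  Fitting minimises the sum of squared
(Z, G) residuals with restarted Nelder–Mead; identifiability comes from the
asymptotic covariance `V = s²(JᵀJ)⁻¹`, reported as per-parameter SD, CV%,
and normal 95 % confidence limits, with near-collinear parameter pairs
flagged.

## Worked example

Generate a synthetic pulse-protocol dataset from the packaged published
estimates, refit the four screened free parameters from a 1.2×-perturbed
start, and summarise:

```python
import zaipp
from zaipp.kinetics import params_to_dict, param_names

za, ag, design = zaipp.scenario_truth("model1_pulse")
obs = zaipp.generate_observations(1, za, ag, design, seed=7)

truth = params_to_dict(za, ag)
free = ("kZY", "rhoZY", "kXGZ", "lambdaGZ")
spec = zaipp.FitSpec(
    model_id=1,
    free_names=free,
    fixed={n: truth[n] for n in param_names(1) if n not in free},
    init={n: 1.2 * truth[n] for n in free},
    normalize=True,
)
res = zaipp.KineticFitModel(obs, spec).fit()
print(res.summary())
```

prints

```
zaipp 0.1.0 — Model 1 (pulse protocol)
observations: 16 scalar values, free parameters: 4
loss J(theta_hat) = 0.0262077   s2 = 0.0186634   converged: True

parameter       estimate          SD       CV%         LLC         ULC
kZY               0.3874      0.1258     32.49      0.1407       0.634
rhoZY              23.23       7.408     31.88       8.714       37.75
kXGZ               2.279     0.05344     2.345       2.174       2.384
lambdaGZ          0.6048      0.2098     34.69      0.1936       1.016
...
derived: kG = 6.162 pmol/mgprot/h, kXGtot = 2.279 /h
```

Read this as: the suppressible elimination rate `kXGZ` is sharply
determined (CV ≈ 2 %), while the uptake rate `kZY`, the μM→pmol/mgprot
conversion `ρZY` (a correlated pair — both get flagged `excluded
(correlated)`) and the suppression constant `λGZ` carry ~30 % CVs from a
single 16-value time course: sparse two-variable sampling leaves much of
the parameter vector only weakly identified, which is exactly what the
identifiability machinery is for.  `res.simulate()` returns the fitted
dense trajectory and `res.plot_fit()` overlays it on the observations.

The same workflow is scriptable from the shell:

```sh
zaipp synth --scenario model1_pulse --seed 7 --out obs.csv
zaipp fit --obs obs.csv --spec fitspec.toml --grid raikkonen_pulse --out fit.json
zaipp identify --fit fit.json --obs obs.csv --grid raikkonen_pulse --out report.json
zaipp simulate --scenario model2_continuous --out trajectory.csv
zaipp run --config pipeline.toml
```

## Package layout

| module                 | contents                                                        |
| ---------------------- | --------------------------------------------------------------- |
| `zaipp.kinetics`       | parameter blocks, right-hand sides, derived rates               |
| `zaipp.simulator`      | RK4 integration, washout event, closed-form ZA oracle           |
| `zaipp.scenarios`      | packaged TOML parameter scenarios and the published sampling grids |
| `zaipp.synthetic`      | observation container and the Gaussian-noise generator          |
| `zaipp.estimation`     | loss, `FitSpec`/`FitResult`, Nelder–Mead fitting                |
| `zaipp.identifiability`| residual Jacobian, `s²(JᵀJ)⁻¹`, SD/CV%/limits, exclusion flags |
| `zaipp.model`          | `KineticFitModel` / `KineticFitResults` front end               |
| `zaipp.cli`            | `zaipp {simulate,synth,fit,identify,reproduce,run}`             |

See `docs/methods.md` for the modelling assumptions, numerical choices and
known limitations.
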