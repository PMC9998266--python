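# fovdesign

How much tissue must a multiplexed-imaging experiment measure to see every
cell phenotype that is there?  Technologies such as imaging mass cytometry
(IMC), MIBI, CODEX and single-molecule FISH image small square fields of
view (FoVs) at high cost, so the number of FoVs `r` and their width `w` are
the design parameters that decide whether rare phenotypes are captured.
`fovdesign` is a toolkit for making that decision quantitatively: it
simulates FoV sampling on labeled point patterns (one record per cell or
spot, with µm coordinates and a phenotype label), fits saturation models of
phenotype recovery, estimates a tissue-intrinsic spatial-segregation
exponent, and turns the fitted parameters into concrete acquisition plans.

## The model

Sampling `r` non-overlapping square FoVs and calling a phenotype *recovered*
when more than `T` of its cells fall inside them produces a saturating
recovery curve, modeled as

    N(r) = N_O · (1 − exp(−r/τ))

where `N_O` is the number of observable phenotypes (those whose total count
exceeds `T`) and `τ` is the characteristic number of FoVs: imaging `2τ` FoVs
recovers `1 − e⁻² ≈ 86%` of the observable phenotypes.  The FoV width enters
through a power law

    τ(w) = C / w^α

whose exponent `α` measures spatial segregation: for phenotypes placed at
random (a homogeneous Poisson process, HPP) the recovery probability is
exactly `1 − exp(−λ r w²)`, hence `α = 2` and only the total imaged area
`r·w²` matters.  Patchy tissues — large domains of identical phenotype —
have `α < 2`, and then splitting a fixed area budget into more, smaller FoVs
recovers strictly more phenotypes.  Two further fitted laws complete the
picture: the decay of the Kullback–Leibler divergence between sampled and
full-tissue phenotype proportions, `KL(r) = KL_O·exp(−(r−1)/θ) + KL_b`, and
the abundance law `τ(p) = A/p^β` linking a phenotype's τ to its proportion.

`α` can also be estimated from a *single* large FoV by progressive
shrinkage: reduce the window about its center and regress `log N(1)` on
`log w`; when few phenotypes are recovered per window (`N(1) ≪ N_O`) the
slope estimates `α`.

## Worked example

```python
import fovdesign as fd

# a synthetic tissue: 5 phenotypes placed at random (HPP, 3e-6 cells/µm²)
ds = fd.generate_hpp_tissue(fd.HppSpec(
    densities={f"P{i}": 3e-6 for i in range(5)},
    extent=(0, 0, 6000, 6000), seed=7,
))

# recovery curve at w = 300 µm and the saturation fit
curve = fd.recovery_curve(ds, r_values=range(1, 16), w=300, T=0, reps=50, seed=1)
print(fd.fit_saturation(curve).summary())

# end-to-end segregation exponent from four FoV widths
scan = fd.fit_alpha_across_widths(ds, [200, 300, 400, 500],
                                  range(1, 16), T=0, reps=50, seed=2)
print(scan.summary())
```

prints

```
Saturation model  N(r) = N_O (1 - exp(-r/tau))
  N_O        5.0031
  tau        3.7413   (2*tau FoVs recover 86% of N_O)
  R^2        0.9870
  converged: True   fallback used: False
  n obs: 15   start values: (20.0, 5.0)
Width scan
  w=   200 um  tau=   8.352  R^2=0.9931
  w=   300 um  tau=   3.899  R^2=0.9982
  w=   400 um  tau=   1.955  R^2=0.9913
  w=   500 um  tau=   1.282  R^2=0.9749
  alpha = 2.0730  (log10 C = 5.7015, R^2 = 0.9975)
```

Reading the numbers: with 300-µm FoVs, τ ≈ 3.7, so about 8 FoVs (2τ)
recover ~86% of the five phenotypes; τ falls with width following
`τ = C/w^α` with α ≈ 2.07 ≈ 2, the signature of spatially random mixing —
for this tissue only the total area matters, not how it is fragmented.
Feeding the fit into the planner,

```python
rec = fd.recommend_design(alpha=scan.alpha, C=scan.power_law.coefficient,
                          target_fraction=0.86, max_r=40)
print(rec.summary())
# Design recommendation (target fraction 0.860)
#   minimal r: r=1, w=800 um, area=0.640 mm^2, fraction=0.874
#   minimal area: r=1, w=800 um, area=0.640 mm^2, fraction=0.874
```

For a segregated tissue (α < 2, e.g. from `generate_segregated_tissue` or a
real tumor section) the same call instead recommends many small FoVs.

A command-line interface mirrors the library:
`fovdesign simulate | sample | fit | alpha | plan` (see `fovdesign --help`).

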