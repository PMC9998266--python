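# Methods

## Sampling model

The object under study is a labeled planar point pattern: one record per
cell (or capture spot) with coordinates in micrometres and a phenotype
label.  An acquisition is simulated by drawing `r` axis-aligned square FoVs
of width `w` whose centers are uniform over the tissue bounds rectangle,
with rejection of any candidate whose square's open interior intersects a
previously accepted square.  A phenotype is *recovered* by a draw when more
than `T` of its points fall inside the union of squares (a `count ≥ T`
variant is available via `strict=False`; the strict rule is the default
reading of "more than T").  Each curve point is the mean over `reps = 50`
independent draws, with the standard error of that mean.

Conventions worth knowing:

* Squares may overhang the tissue edge.  Centers are sampled on the bounds
  rectangle, so a square near the border captures slightly less tissue.
  This follows the most literal reading of "pick a random point, draw a
  square around it".  The cost is a small width-dependent attenuation of
  the effective captured area (expected factor `(1 − w/(4L))²` for a square
  tissue of side `L`), which biases width-law exponents downward by a few
  hundredths at `w/L ≈ 0.1`.  Tissues much larger than the FoV make it
  negligible.
* Point membership in a square is half-open, `[x−w/2, x+w/2) × [y−w/2,
  y+w/2)`, so squares sharing an edge never double-count a point; squares
  sharing only an edge are not considered overlapping.
* Draws at different `r` are independent (fresh random substream per
  `(r, repetition)` from a spawned `SeedSequence`); no global random state
  is used anywhere.
* Placement gives up after 1000 consecutive rejections for one square
  (`max_attempts`), raising an explicit error.  Note that random sequential
  placement of non-overlapping squares jams well below full coverage
  (around half of the available area), so feasible `r` grids must shrink
  roughly like `1/w²` as the width grows; `fit_alpha_across_widths`
  accepts per-width `r` grids for exactly this reason.

## Fitted models

All nonlinear fits are Gauss–Newton-class least squares
(`scipy.optimize.curve_fit`); all R² values are the squared Pearson
correlation between observed and fitted values.

* **Saturation** `N(r) = N_O(1 − exp(−r/τ))`, start values `(N_O, τ) =
  (20, 5)`.  For a single HPP phenotype of density λ and `T = 0` the model
  is exact with `τ = 1/(λw²)`; for a mixture of phenotypes with broadly
  similar densities it is a serviceable approximation.  It is *not* a good
  model when one density meets a large threshold head-on (the recovery
  curve then turns sigmoidal), nor when phenotype abundances span orders of
  magnitude.
* **Width law** `τ(w) = C/w^α` and **abundance law** `τ(p) = A/p^β`:
  ordinary least squares on `log10`-transformed data (statsmodels OLS);
  the exponent is the negated slope.
* **KL decay** `KL(r) = KL_O·exp(−(r−1)/θ) + KL_b`, start values
  `(θ, KL_O, KL_b) = (2, 1, 0.01)`.  KL divergence uses natural logarithm
  with `0·log 0 := 0`; draws that capture no cells at all are rejected and
  redrawn (tallied in `kl_rejections`).
* **Shrinkage estimator**: shrink one FoV about its center by factors
  `1.1, 1.2, 1.5, 1.8, 2.2, 2.5, 3.0`, count recovered phenotypes per
  window, regress `log(count)` on `log(effective width)` (geometric-mean
  side length for non-square windows).  The slope estimates α through the
  approximation `log(1 − N(1)/N_O) ≈ −N(1)/N_O`, valid when single-window
  recovery is sparse; estimates with regression R² < 0.9 are flagged
  (`passed_quality=False`) and should be excluded from cohort medians.
  `T` is held constant while shrinking.

### Numerical choices

The fixed start `(20, 5)` can land in a step-function local minimum
(`τ → 0`) when the true τ is far below it, or drift along the degenerate
ridge `N_O, τ → ∞` (constant `N_O/τ`) when the data lack curvature.  The
fitter therefore also starts from a data-driven moment initialiser
(asymptote from the curve maximum, τ from the first curve point) and keeps
the lowest-SSE solution; a positivity-bounded trust-region fall-back runs
only if every unbounded attempt diverges, and a failed fit is reported with
`converged=False` rather than raised.  Exactly-model-generated data are
unaffected by the multi-start.

`fovs_for_fraction` inverts the saturation law to the smallest integer
`r ≥ −τ·ln(1−f)`, snapping values within 1e-9 of an integer before taking
the ceiling so that `f = 1 − e⁻²` returns exactly `⌈2τ⌉`.

The design surface is `fraction(r, w) = 1 − exp(−r·w^α/C)` (the exponent is
negative: a positive exponent would not be a probability and would
contradict the two laws it is derived from).  Widths are µm; total areas
are reported in mm² with the 10⁻⁶ conversion handled internally.

The gene-selection deviance is computed exactly as conventionally printed
for this filtering step, `D(x) = Σ xᵢ·ln xᵢ + n·ln n`; note it omits the
expected-count terms of a textbook multinomial deviance and is a ranking
score, not a calibrated statistic.

## Synthetic tissues

`generate_hpp_tissue` draws each phenotype as an independent homogeneous
Poisson process (count `~ Poisson(λ·area)`, positions uniform).  It is the
ground-truth case for every closed-form check: recovery probability
`1 − exp(−λrw²)`, `τ = 1/(λw²)`, `α = 2`.

`generate_segregated_tissue` scatters disk-shaped patches (centers uniform,
one label per patch drawn from a pool, `Poisson(ρπR²)` points uniform per
disk, clipped to the extent) over a uniformly mixed background.  Disk
patches with hard label assignment are the simplest mechanism that provably
lowers α; patch count, radius, density and background level tune the
segregation strength.

Two regimes of this generator back the consistency checks, chosen to
respect each estimator's stated assumptions:

* *Threshold robustness* uses dense patches (ρ = 0.03/µm², R = 100 µm,
  ~940 points per patch), so thresholds of 20–70 cells correspond to only
  2–7% of a patch — recovery is then governed by patch geometry and the
  fitted α is threshold-insensitive.  Thresholds are compared on shared
  sampling draws (recovery is a pure function of the per-draw counts), so
  the comparison isolates the threshold effect.
* *Shrinkage consistency* uses sparse per-phenotype patch counts (30
  phenotypes, 6 patches each) so that a single 600-µm window recovers only
  a small fraction of the phenotypes, the `N(1) ≪ N_O` regime the log
  approximation needs.

What these synthetic tissues do **not** emulate: expression noise,
imaging artefacts, realistic tissue morphology (patches are disks, not
anatomical domains), density gradients, or cell–cell interaction
structure.  Passing tests on them demonstrates the correctness and internal
consistency of the estimators under their stated assumptions — not that a
particular real tissue satisfies those assumptions.

`generate_curve_observations` samples recovery curves directly from the
saturation law (`Binomial(N_O, 1 − e^{−r/τ})` per draw) for exercising the
fitting layer in isolation.

## Problem sizes used in the checks

End-to-end checks run at desk scale: HPP tissues of a few hundred to a few
thousand points on 6 × 6 mm (λ = 3 × 10⁻⁶/µm² per phenotype puts
τ between ~8 and ~1.3 across widths 200–500 µm, inside an `r = 1..15`
grid), segregated tissues of 50k–200k points on 4 × 4 mm, 50 repetitions
per curve point throughout.  The end-to-end α of an HPP tissue is reported
as the median over seven independent tissue replicates: a single replicate
has a Monte Carlo spread of about ±0.1 (dominated by shared FoV-placement
noise, which averaging over phenotypes cannot remove), and the median is
robust to an occasional degenerate per-width fit.

## Known limitations

* The saturation model assumes roughly comparable phenotype densities;
  strongly heavy-tailed abundance distributions break the single-τ
  description.
* α from the width law and α from shrinkage agree only in the sparse
  recovery regime; saturated single windows flatten the shrinkage slope.
* Cell–cell interactions and multicellular structures are outside the
  model: recovering all phenotypes is not the same as recovering all
  spatial motifs.
* Coordinates must be physical micrometres; converting array indices or
  spot lattice positions is the caller's responsibility.
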