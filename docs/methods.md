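# Methods

## Scope and model of the problem

`refinery` implements the decision layer of an automated macromolecular
crystal-structure optimization pipeline.  Given deposited coordinates, the
reflection data and a refinement engine, the pipeline must answer, without
human supervision: is the input reproducible; is the cross-validation set
trustworthy; how many displacement parameters can the data support; which
restraint weights should be searched; which of a set of candidate
refinements is genuinely better rather than overfitted; and which model
parts are safe to prune or rebuild.  The reciprocal-space refinement
itself is *not* implemented — it sits behind a three-operation engine
contract (`refine`, `rigid_body`, `tls_refine`), each deterministic for
fixed inputs and settings, so every decision path can be exercised with a
simulated engine.

## Core quantities

For observed and calculated structure-factor amplitudes,

    R = Σ|F_obs − m·F_calc| / Σ F_obs,

with the linear scale m chosen to minimize the absolute residual
(golden-section search on the convex piecewise-linear objective,
terminated at a relative bracket width of 1e−12, which makes R invariant
under rescaling of F_calc to well below 1e−9).  R_free is the same
quantity over a held-out test set.  Derived guards:

* σ(R_free) = R_free / √(2·N_test);
* R_free,unb = R × R_ratio, the expectation for a converged, unbiased
  refinement, with R_ratio = √[(N_obs + N_param)/(N_obs − N_param)] by
  default — the classical unrestrained data-to-parameter approximation.
  The true restrained-refinement ratio depends on the effective restraint
  count, which the engine may know; every consumer therefore accepts an
  externally supplied R_ratio instead;
* Z(R_free) = (R_free,unb − R_free)/σ(R_free), positive when the model is
  better than expectation (terms swapped for the lower-is-better metric).

## Decision rules and their constants

All numeric decision constants are module-level values with the semantics
they have in production pipelines of this kind: free sets are rejected
below 500 reflections or above 25% of the data; created sets target 5%,
raised toward 1000 reflections, capped at 10%; a recalculated R_free is
biased if the set was new, R_free < R, Z(R_free) > 10, or the R_free − R
gap shrank below 0.33× the header gap; B-factor parameterization routes
on reflections per atom at 18 / 13.5 / 3; the Hamilton acceptance bands
are 30% / 95% with overrefinement cutoffs Z < −3 and gaps of 4 (aniso) /
6 (iso) percentage points and the 2.0× gap-ratio test; the picker caps
R_free,max at R + 6 points with a 3.5σ allowance; waters prune below a
weighted-mean density fit of 0.37; the baseline ladder engages above a
5-point R gap and aborts above 10 points; twin targets require an
external twin fraction > 5% plus an operator with R_merge < 44% and
fraction > 7%.  Boundary semantics (strict versus inclusive) follow the
rule statements literally; the test suite pins every boundary with
straddling inputs.

## Parameters that are genuinely open, and the choices made

* **Restraint-weight grids per category.**  Only the existence, the
  resolution dependence and the maximum length (7) of the search spaces
  are prescribed.  Defaults here are log-spaced: 7 weights spanning
  5.0–0.05 for atomic/high, 6 spanning 3.0–0.03 for medium, 4 spanning
  1.0–0.03 for low, 3 spanning 0.5–0.05 for vlow, and a single
  automatic-weighting sentinel (0.0) for xlow.  Lower-resolution data get
  tighter, shorter grids because loose weights destabilize refinement
  there.  All grids are overridable from a YAML config
  (`{category: {weight_grid: [...], b_weight_grid: [...]}}`).
* **Hamilton weight-assumption grid.**  w1, w2 each sweep 0.0–1.0 in
  steps of 0.1 (121 tests) at α = 0.05; both configurable.  The
  hypothesis dimension b = Δparams − w2·N_extra is floored at 1 to keep
  the F quantile defined; grid points with non-positive free degrees
  count as rejections, since an under-determined complex model cannot be
  justified.
* **Density-fit kernel.**  The taper is linear, t(x) = max(0, 1 −
  |x − x_a|/r_atom), atoms weighted by occ/(1 + U) with U = B/8π², scores
  evaluated on grid points without interpolation.  The kernel is a
  pluggable strategy; the 0.37 pruning cutoff is therefore exercised
  against the decision rule with injected scores, not against a specific
  kernel.  Default radii: C 1.7, N 1.55, O 1.52, S 1.8 Å, fallback 1.7 Å,
  overridable per call.
* **Cycle-rule interactions.**  The re-refinement cycle rules are listed
  without an interaction order; precedence here is legacy > anisotropic >
  new-free-set > default, and the "+5 cycles without TLS" applies only to
  the 20- and 30-cycle bases.  This ordering reproduces every printed
  single-condition count.
* **Tie-breaking in the picker.**  Exact Z ties resolve to the lower
  R_free, then to input order; an undefined Z (σ = 0 or no R_ratio) loses
  the final comparison, and such candidates pass the R_free,max filter
  only through the R + 6-point cap branch.  Determinism is required
  because the pipeline trace must be byte-reproducible.
* **Status-flag dialects.**  Free-set columns in {o/f} letters, {1/0}
  integers, and multi-valued integer flags (0 = free) are accepted; for a
  pure {0,1} column the minority class is taken as free, and a wrongly
  guessed inverted set is caught downstream by the swap rule.

## The synthetic generators

The generators emulate exactly what the decision layer consumes, not the
underlying physics.  Reflections: unique Miller indices of a P1 toy cell
sized so the resolution sphere holds the requested count, amplitudes from
Wilson statistics (exponential intensities), σ = 5% fractional error with
jitter, a 5% deposited free set, and optional planted defects (negative
amplitudes, zero σ, duplicate datasets) for sanitation tests.  The
simulated engine's R_free response is quadratic in the log restraint
weight around a planted optimum (default curvature 0.01 per decade²,
R_free 0.22 at the optimum, R_free − R = 0.04), geometry r.m.s. Z grows
linearly as restraints loosen (0.10 per decade from 0.80/0.90), TLS and
anisotropic B factors shift R_free by configured increments, and the free
likelihood is a monotone transform of R_free.  Density maps are Gaussian
sums with waters planted in peaks and in flat solvent.

What passing tests therefore show: the decision algebra — every branch,
boundary and selection — is correct on inputs whose ground truth is known
by construction.  What they do not show: behaviour under real,
resolution-dependent noise, model errors correlated with geometry, or a
real refinement program's convergence behaviour; no claim is made about
population-level improvement statistics on deposited structures.

## Problem sizes and numerics

Default test problems use 300–13 000 reflections and 300–1000 atoms;
planted-optimum recovery runs the full pipeline on 100 seeds at 4000
reflections / 300 atoms.  All randomness flows from explicit seeds
through `numpy.random.default_rng`; pipeline traces serialize with sorted
keys and floats rounded to 12 decimals so same-seed runs are
byte-identical.  Completeness counts symmetry-unique reflections with
Friedel pairs merged, inclusive of the resolution limit (d ≥ d_min).
Degenerate inputs (empty reflection lists, σ = 0, vanished free sets,
models stripped to nothing) raise typed errors or take documented
fallback branches rather than propagating NaNs.

## Known limitations

* The engine adapter for an external refinement binary is a documented
  contract only; no subprocess driver ships here.
* Intensity-to-amplitude conversion, twin-fraction estimation, Wilson-B
  computation and geometry validation reports are treated as inputs from
  external tools, as in the production setting.
* NCS handling, chirality fixing and water *addition* are out of scope.
* mmCIF coordinate input is not supported (PDB-format era pipeline);
  reflection data are mmCIF.
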