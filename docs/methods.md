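# Methods

## Signal model

An event-related skin-conductance segment, taken as the 10 s following
stimulus onset (averaged across subjects per stimulus when replicate
segments are available), is modelled as

```
y(t) = f(t) + a0·exp(−t/t_d) + c
f(t) = g · exp(−(t − T_os)/t_d) / (1 + exp(−(t − T_os)/t_r))
```

with six free parameters: the pure-SCR gain `g ≥ 0` (μS), onset latency
`T_os ≥ 0` (s), rise time `t_r > 0` (s), decay time constant `t_d > 0` (s),
the previous-response amplitude at onset `a0 ≥ 0` (μS) and the tonic level
`c ≥ 0` (μS). The sigmoid factor governs the rising limb, the exponential
the recovery; `f` is non-negative and vanishes as `t → ∞` for every valid
parameter set. Keeping the model at six parameters forces the
previous-response tail to share the SCR's decay constant `t_d`; this is a
modelling economy, not a physiological claim, and is the main reason the
tail term should be read as a local correction rather than a full
deconvolution (one SCR per segment is assumed; overlapping-event
deconvolution is out of scope).

Two properties of this waveform matter in practice and drive several design
choices below: it carries substantial mass *before* `T_os` (the sigmoid is
at half height at the nominal onset), and on a decaying previous-response
limb the summed signal can be monotone even though an SCR is present.

## Parameter extraction

Fitting is damped least squares (Marquardt–Levenberg): at each iteration
the step solves `(JᵀJ + λ·diag(JᵀJ)) δ = −Jᵀr` and is accepted only if the
SSE decreases, so the returned SSE never exceeds the starting one. The
iteration count is the number of accepted steps, capped at a configurable
maximum (default 20, the classical setting for this pipeline; the recovery
tests use 200 to reach machine-precision optima). Convergence is declared
when the relative SSE drop falls below 1e−8. Strictly positive parameters
(`t_r`, `t_d`) are optimized as logarithms; non-negative ones (`g`, `T_os`,
`a0`, `c`) are clipped at zero on decoding. The Jacobian is forward-difference.

The starting point combines the obvious moment heuristics (tonic level =
segment minimum, `a0` = onset value above it) with a small grid over
(`T_os`, `t_r`, `t_d`) candidates at which the amplitudes (`g`, `a0`, `c`)
— in which the model is linear — are solved by least squares; the
lowest-SSE candidate starts the damped iteration. The bare argmax-of-slope
onset heuristic alone is kept as a candidate but is unreliable precisely in
the monotone-trace regime described above.

On noiseless synthetic segments the fit recovers all six parameters to
machine precision; at a realistic sensor noise of 0.01 μS the gain is
recovered with ≈2% median error at 100 Hz sampling. At 10 Hz (100 samples
per segment) the Fisher information bounds the gain's relative standard
error near 8% at that noise level — no optimizer can beat this — which is
why coarse-rate checks use a 10% tolerance.

## Data extension

From a class column `ξ_1..ξ_n` the construction
`η_ij = μ + (ξ_i + ξ_j − 2μ)/√2` over all unordered pairs `i < j`
(lexicographic, deterministic) yields `n(n−1)/2` values with the same mean
and variance as the population; two η sharing a source index correlate at
0.5, disjoint pairs at 0, and `η_ij` correlates with its own sources at
`1/√2`. These statements hold for the *population* mean `μ`. In application
`μ` is unknown and the plug-in sample mean is used, which perturbs the
structure at order `1/n` (at n = 8 the η variance shrinks to ≈0.875 σ² and
the overlap correlation to ≈0.43). The `extend_column(..., mu=...)`
parameter exists so the exact claims can be verified by simulation with a
known mean; the applied pipeline always uses the plug-in form.

Whole tables are extended per affect class with a *shared* pair index
across columns, so each simulated row is an internally consistent
pseudo-stimulus and the joint (gain, decay-constant, rating) class pattern
survives. Because the map `ξ → η` is affine, affine relations between
columns survive extension exactly; nonlinear relations survive only
approximately (second order in the within-class spread). Extended ratings
are clipped back into [1, 9] (rarely binding with mid-scale classes; can be
disabled).

## Polynomial regression, truncation, pruning, selection

A p-th order polynomial in m variables has `C(m+p, m)` monomials
(graded-lexicographic basis). The design matrix on raw units (μS, s — no
silent standardization, so coefficients live in interpretable units)
becomes numerically singular at high order; the solver zeroes singular
values below `singular_criterion` (default 1e−8) *relative to the largest*
— an absolute cutoff would not be scale invariant — and returns the
minimum-norm solution on the retained subspace. Standard errors come from
the truncated-pseudoinverse covariance with residual degrees of freedom
`n − rank`; when the fit is saturated the p-values are reported as NaN
rather than invented. An optional `standardize` switch equilibrates design
columns to unit norm before truncation (affecting only the truncation
decision; coefficients are mapped back to raw units).

Insignificant terms are removed by backward elimination: repeatedly drop
the single worst term with `p > significance_level` (default 1e−4) and
refit, until all retained terms are significant or only the intercept
remains. The intercept is exempt — removing it would force the surface
through zero, which is meaningless on a 1–9 rating scale. One-shot pruning
was the plausible alternative; iterative refitting was chosen because each
removal redistributes significance among collinear monomials.

Order selection fits each candidate order on the extended (simulated) rows
and scores it by `Index = r/MSE` on the experimental rows — training on
simulated, verifying on experimental keeps the small experimental set as an
honest evaluation set. Ties break toward the lower order; an exact fit
(MSE = 0) scores `inf` (a documented sentinel), and models with constant
predictions (undefined r) are reported with NaN metrics and never selected.
The Pearson CI is Fisher-z with `1/√(n−3)` standard error, flagged
approximate and never used for decisions. Gradients of the fitted surface
are analytic (exponent-weighted term shifts), evaluated pointwise or on a
rectangular grid over the observed (gain, decay-constant) bounding box.

## Synthetic study conditions

The default generator emulates a 3-class (pleasant / neutral / unpleasant)
× 8-stimulus design. Class centres in (g, t_d): (0.9, 5.0), (0.4, 3.0),
(1.1, 2.0) with SDs (0.08, 0.30); onset ≈1.0–1.5 s, rise ≈0.6–0.8 s
(truncated-normal draws, redrawn at or below zero). Ratings come from a
known order-2 ground-truth map — arousal gain-dominated
(`A ≈ 0.82 + 4.47 g + 0.13 t_d`), valence mixed with a gain×decay
interaction (`V ≈ 4.22 − 4.37 g + 0.44 t_d + g·t_d`) — placing class rating
centres near V 7/5/2.5 and A 5.5/3/6, plus Gaussian rating noise (SD 0.3,
clipped to [1, 9]). Traces are the six-parameter model on a 10 s, 100 Hz
grid (`a0` ~ U(0.1, 0.5), `c` ~ U(1.0, 3.0)) plus 0.01 μS sensor noise.
These maps are synthetic: they echo the qualitative finding of a
gain-dominated arousal surface, and are not published coefficients.

Because the extension is affine, an exact closed loop
(extend → fit → evaluate hitting r = 1) is only possible when the
generating map is affine; `linear_affective_config()` provides that
noise-free variant (same class centres) for closed-loop checks, while the
order-2 default exercises order *selection*.

What the generator does **not** emulate: subject-level variability and
habituation, overlapping SCRs within a segment, movement artifacts,
non-Gaussian sensor noise, and any empirical (g, t_d) → affect relation.
Passing tests therefore demonstrate the correctness and statistical
behaviour of the estimation machinery under its stated assumptions, not the
physiological validity of the affective mapping on real recordings.

## Degenerate inputs and numerical edges

Flat traces yield a tonic-only initial guess (amplitude floors keep
`t_r, t_d` positive); segments with fewer than 7 samples are rejected as
underdetermined; waveform evaluation is done in log space with a clamp so
extreme trial parameters during fitting produce large finite values rather
than overflow. Zero-variance inputs to the correlation raise a dedicated
error (they are undefined, not zero); zero-variance samples are fixed
points of the extension. Model files serialize floats via `repr` and
round-trip bit-exactly.

## Problem sizes

Default test and demonstration sizes — 24 stimuli, 84 extended rows, 10 s
segments at 100 Hz, 10,000 replicates for the moment/correlation
simulations, order sweeps up to 9 — were chosen as the natural scale of the
emulated study design; the full suite runs in a few seconds on one core.

## Known limitations

- The shared decay constant between SCR and previous-response tail biases
  fits when the true tail decays on a very different time scale.
- Backward elimination with t-tests on a truncated pseudoinverse is a
  heuristic; collinear monomial bases can prune a term whose effect is
  real but absorbed by neighbours.
- The plug-in extension slightly deflates variance at small n (see above);
  training-set moments are not exactly those of the source class.
- Index = r/MSE is dimensional (rating-units⁻²); it ranks models on a fixed
  evaluation set but is not comparable across targets or scales.
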