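# Methods note

This note records the model behind the package, the numerical choices that
matter for reproducibility, and the known limitations.  Notation follows
the README: ψ(h) is an agent's characteristic curve over difficulty h on
[origin, q], Ψ the capability, M the first partial moment, S the spread,
γ the normalised generality.

## Model and estimands

Each agent's responses are accomplishment values in [0, 1] on items with a
real-valued difficulty.  The characteristic curve is the conditional mean
of accomplishment given difficulty; the package estimates it by averaging
responses at each observed difficulty value (or difficulty bin) and
interpolating between the resulting points.  All summary quantities are
integrals of that estimated curve:

- Ψ = ∫ ψ(h) dh over [origin, q] — area under the curve;
- M = ∫ (h − origin) ψ(h) dh — first partial moment about the origin;
- ℍ = origin + M / Ψ — expected difficulty of the agent's successes
  (undefined when Ψ = 0);
- S = √(2M − Ψ²) — zero exactly when the curve is a left-compacted unit
  step of width Ψ;
- Γ = 1 / S (∞ for a perfect step);
- γ = −s with s = sign(S² − S²const) · √(|S² − S²const| / (Ψ(q − Ψ))) and
  S²const = Ψ(q − Ψ).  This signed-root normalisation maps the constant
  curve to γ = 0, the decreasing step to +1 and the increasing step to −1,
  and is monotone in S at fixed Ψ.  γ is undefined at Ψ ∈ {0, q}, where
  S²const = 0 and every isometric collapses to a single point; such agents
  are reported with `defined = False` rather than an arbitrary value.

Agents with γ < 0 are classified *abstruse*: their success mass sits at the
hard end of the range.

## Curve construction

**Binning.**  With at most 25 distinct difficulty values the curve uses one
point per value ("identity" binning), averaging responses at tied
difficulties.  Beyond that, the default is 10 equal-width bins over
[origin, q], represented at bin midpoints; empty bins are skipped and the
curve spans the gap.  Both rules can be overridden (`bins="identity"` or an
integer).  Outside the observed difficulty range the curve is extended
constantly to the boundaries, so a curve observed only on an interior
interval still integrates over the full range.

**Interpolation modes.**  Between curve points three readings are offered:

- `linear` (default): the trapezoidal reading; natural for graded
  accomplishments and smooth psychometric curves.
- `previous`: a staircase that holds each value until the next observed
  difficulty.
- `nearest`: a staircase that switches at the midpoints between
  consecutive observed difficulties — the unbiased discrete reading.

The staircase modes exist because binary response matrices on a finite set
of difficulty levels genuinely are step functions between levels.  Under
`linear`, a perfectly difficulty-ordered (Guttman) agent acquires a
one-level-wide linear ramp at its threshold; the ramp contributes a spread
of width/√12, so γ approaches but never reaches 1 no matter how many
agents or levels are used (for M difficulty levels the weakest agent gets
γ ≈ 1 − 1/(12M)).  With `nearest` the recovery is exact, which is why the
Guttman verification tests use it.  `previous` biases each level's
influence to the right, which pushes an agent whose first failure is the
hardest level to Ψ = q (undefined γ); `nearest` does not have this
problem and is the recommended staircase.

**Discontinuities.**  Reference curves with true jumps (step agents) are
represented exactly by duplicated abscissae carrying the one-sided limits
(`ACC.from_function(..., jumps=(theta,))`).  A jump sampled on an n-point
grid instead produces a one-cell ramp and a γ error on the order of
(q/n)²/12 / Ψ — about 1.7·10⁻⁷ for a mid-range step on a 1001-point grid —
which is why the analytic anchors are computed with the jump encoding.

## Numerical integration

Ψ uses the trapezoid rule, which is exact for the piecewise-linear
interpolant.  M is *not* computed by applying the trapezoid rule to sampled
h·ψ(h) values: on a linear segment that product is quadratic, and the
naive rule overestimates each segment's moment.  The error looks harmless
(second order) but has a definite sign, and near step-like curves it can
push the invariant 2M − Ψ² below zero by ~10⁻⁵ — far beyond round-off.
Instead each linear segment contributes its exact moment

    (h₁ − h₀) · ((2u₀ + u₁)ψ₀ + (u₀ + 2u₁)ψ₁) / 6,   u = h − origin,

which keeps 2M − Ψ² non-negative up to genuine floating-point error.  The
remaining round-off is clamped to zero within a relative tolerance of 10⁻⁹
of max(q², 1); a more negative value raises
`IntegrationInconsistencyError` instead of being masked, since it signals
an integration bug rather than round-off.  Note that the signed square
root in γ halves the exponent of any residual round-off: a 10⁻¹⁵ error in
S² appears as ~10⁻⁸ in γ near γ = 0, which is why near-zero γ assertions
in the test-suite use 10⁻⁶ tolerances.

## Extrinsic difficulty transformations

All five transformations produce a (possibly binarised) matrix plus
difficulties on a shared scale:

- **opponent**: for pairwise win/loss matrices, an opponent's difficulty is
  its mean score across its own row.
- **reference agent**: responses binarised at "scores at least as well as
  the reference"; item difficulty is the fraction of the population scoring
  *strictly worse* than the reference (a `direction="reference"` flag
  flips the comparison to strictly-better-than).
- **rank**: each item expands into c columns, one per rank threshold l;
  the cell is 1 when the agent reaches the l-th best score, and the
  threshold's difficulty is (c − l + 1)/c, so the top rank is hardest.
- **reference distribution**: each item expands into c columns at the
  k/(c+1) quantiles (linear-interpolation quantiles) of a reference sample;
  the cell is 1 when the agent's score strictly exceeds the quantile.
  Works for a single agent, since difficulty comes from the reference, not
  the population.
- **failure-rate proxy**: difficulty = logit of the item's failure rate,
  clipped to [1/(2M), 1 − 1/(2M)] for M agents so items everyone passes or
  fails stay finite, then shifted so the easiest item sits at zero.

## Instance hardness

- `kdn`: fraction of an instance's k nearest neighbours (Euclidean, on
  z-scored features by default, self excluded) with a different label.
  Ties at the k-th neighbour are broken deterministically towards the
  lower instance index (implemented with a stable argsort; verified
  against a brute-force all-pairs oracle).
- `tdu`: leaf depth of each instance in one unpruned binary decision tree
  (root depth 0).  Splits maximise entropy gain over midpoints between
  consecutive distinct feature values, with ties broken by (feature index,
  threshold).  When a node is impure but no split strictly reduces entropy
  (XOR-structured data), the first candidate split is taken anyway, so the
  tree keeps growing until leaves are pure or no feature has two distinct
  values; identical feature rows with mixed labels stop early.

## Synthetic agents

The simulator provides step (success iff h ≤ θ), reverse-step (success iff
h ≥ q − θ), constant, Bernoulli, probit Φ((θ − h)/σ) and
subdomain-specialist models, with `draws="expected"` (deterministic
probabilities) or `draws="bernoulli"` (seeded binary draws).  These are
deliberately idealised: they exist to give the pipeline agents with known
ground truth (a step agent must come out with Ψ = θ, S = 0, γ = 1; a
probit agent's spread must equal σ when θ sits well inside the range), not
to model any real population.  Realistic response data will mix
difficulty-dependent and item-specific variance that none of these
one-parameter families capture.

## Limitations

- The curve estimate inherits binning bias: with few items per bin the
  bin means are noisy, and the default 10-bin rule can smear a sharp
  threshold.  The random-agent verification (2000 items, 100 seeds) bounds
  the resulting |mean γ| at 0.1, not at zero.
- The probit spread-equals-σ identity holds only when the curve's mass is
  well inside [0, q]; with θ near a boundary the truncation inflates or
  deflates S.
- Extrinsic difficulties are population-relative: adding agents changes
  the rank/reference difficulties (though never the metrics of an agent
  *given* fixed difficulties — the decoupling the package guarantees).
- γ compares an agent only against curves of the same capability.
  Comparing γ across agents with very different Ψ, especially near the
  range extremes where γ is undefined, is not meaningful.
- The SLODR median-split diagnostic is descriptive; it reports group means
  and no significance test.
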