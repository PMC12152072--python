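# Methods

## Model and assumptions

The mean response is the three-parameter Emax (Hill-type) curve
`eta(x, theta) = theta0 + theta1 x/(x + theta2)` observed with independent
Gaussian errors of **known** standard deviation `sigma` at doses in `[a, b]`,
`a >= 0`. `sigma` is a user input everywhere; no estimation pathway for it
exists in the package (the simulation engine likewise fixes it). On the
Cartesian plane the curve is the concave branch of a hyperbola with vertical
asymptote at `x = -theta2` and horizontal asymptote `theta0 + theta1`.

The admissible parameter set is the set of increasing concave branches on
`[a, b]`: `theta2 > -a` together with `theta1 * theta2 > 0`. For `a = 0` this
is the familiar `theta1 > 0, theta2 > 0`; for `a > 0` it also contains curves
with the vertical asymptote inside `(-a, 0)`, where `theta1 < 0`. These are
awkward in the original coordinates but natural in the shifted
parametrization `x_tilde = x - a`,

```
t0 = theta0 + a*theta1/(theta2 + a),  t1 = theta1*theta2/(theta2 + a),  t2 = theta2 + a,
```

where admissibility is simply `t1 > 0, t2 > 0`. `t0` is the mean response at
the lowest dose and `t1` the maximum effect relative to it. The two maps are
exact algebraic inverses and the curve is unchanged; all estimators are
available in both coordinate systems.

## Existence geometry and the closed-form MLE

With known `sigma` the per-dose counts `n_i` and means `ybar_i` are
sufficient, and the MLE minimizes `sum_i n_i (ybar_i - eta(x_i, theta))^2`.
For a three-point design the minimizer exists iff the three means have an
increasing concave shape (`ybar1 < ybar2 < ybar3`, chord slopes
`m1 = (ybar2-ybar1)/(x2-x1) > m2 = (ybar3-ybar1)/(x3-x1)`), in which case it
interpolates them exactly:

```
t0 = ybar1,   t1 = m1 m2 (x3 - x2) / (m1 - m2),   t2 = (ybar3 - ybar2) / (m1 - m2).
```

Otherwise the infimum of the SSE is approached only along sequences of Emax
curves converging pointwise to a limit function outside the model: an
increasing straight line (`t2 -> inf` with `t1/t2` fixed), a horizontal line
(`t1 -> 0` or `t1 = o(t2)`), or a step at the lowest dose (`t2 -> 0`). The
package certifies non-existence by returning the dominating limit function:
the step `(ybar1, ybar23)` for concave non-increasing data with
`ybar1 < ybar23` (the pooled mean of the upper doses), the flat line at the
overall weighted mean for `ybar1 >= ybar23` or for convex data whose weighted
regression slope `m0 <= 0`, and the weighted regression line itself for
convex data with `m0 > 0`.

Boundary ties (`m1 = m2`, `ybar1 = ybar23`, `m0 = 0`) follow the defining
inequalities literally (`<=` goes with the convex/flat branch) and are
evaluated in exact floating comparison — they have probability zero under
continuous data, and a deterministic convention beats a tolerance. Data
classified increasing-concave but close to the boundary produce legitimate,
very large `t2`; no clamping is applied, and a diagnostic flag
(`t2_near_boundary`, threshold `1e6*(b-a)`) marks fits that are numerically
indistinguishable from a limit class.

## Firth's modified score

The score adjustment `A_t = (1/2) trace(I^{-1} Q_t)` (the `P_t` term of the
general theory vanishes for Gaussian nonlinear regression) reduces for the
Emax model to closed forms in the design moments
`M[l1,l2] = E_xi[x^l1/(theta2+x)^l2]`; `A` depends only on the design weights
and `(theta1, theta2)` — not on `n` or `sigma` — while the score scales as
`n/sigma^2`, so the modification vanishes asymptotically. There is no
penalized likelihood behind `U* = U + A` (its Jacobian is asymmetric), so the
equations are solved as a root-finding problem, not an optimization:

* coordinates `(theta0, log theta1, log(theta2+a))` keep iterates admissible;
* deterministic multi-start: `theta0 = ybar1`,
  `theta1 = max(ybar3-ybar1, eps)`, `theta2` in `{x2/4, x2, 2*x2, b}`, plus
  the closed-form MLE plug-in when it lands in the admissible region; Powell
  hybrid iterations from each start in order, first admissible root wins
  (every multi-root probe we ran found the same root, and a fixed order keeps
  the result reproducible);
* admissibility: converged with
  `||U*||_inf < 1e-6 * (n/sigma^2) * max(1, max|ybar|)`, `theta1 > 1e-8`,
  `theta2 > -a + 1e-8` and `|theta2| < 1e6 * b`. "No admissible root" is a
  reported outcome, never an exception — on convex data near a true Emax
  curve the solver essentially always succeeds, on concave non-increasing
  data it essentially never does, which is precisely the practical value of
  the classification.

## Region probabilities

Since `ybar_i ~ N(eta(x_i), sigma^2/n_i)` independently, each shape region is
a polyhedral event `A ybar < 0` whose rows are *contrasts* (rows sum to
zero). The three-dimensional Gaussian integral is therefore degenerate, and
we compute it exactly in the contrast coordinates
`(u, v) = (ybar2-ybar1, ybar3-ybar1)`: each region is a cone in the plane,
and its probability is a single adaptive quadrature over `u` of the
conditional-normal mass of the `v`-slice (absolute tolerance `1e-10`,
integrand truncated at 12 standard deviations). This replaces a generic
trivariate-normal CDF backend: it is deterministic (no quasi-random seed),
faster, and accurate to well below the `1e-4` reporting precision. The convex
region needs only a univariate normal CDF. The four region probabilities sum
to one up to integration error; the Case-1 probability is computed as the sum
of its two subcase cones.

The power function `beta(theta2; x2)` of the test that rejects
`H0: theta2 >= theta2_guess` when Case 1 is observed is the Case-1
probability with `theta2` substituted. It is increasing in `x2` (placing the
middle dose higher makes a non-increasing pattern more likely), so
`x2_for_alpha` inverts `beta(theta2_guess; x2) = alpha` by bisection on
`[a + 1e-6 (b-a), (a+b)/2]` with dose tolerance `1e-8`. Note `beta` is
decreasing in `theta2` on the alternative side but rises again far above the
guess, where the effect size `~theta1(b-a)/theta2` sinks into the noise; the
reported `alpha = beta(guess; x2)` is the level at the boundary of `H0`, as
defined. After a Case-1 outcome, `recommend_augmentation` proposes new
observations at `x*(theta2_new)` inside `(a, x*(theta2_guess))`; the default
`theta2_new = theta2_guess/2` is a flagged convention (any value below the
guess is defensible), exposed as a parameter.

## Synthetic data and the simulation study

`StudyConfig` defaults are the reference study conditions: `a = 0.001`,
`b = 150`, true `theta = (2, 0.467, 50)`, `sigma = 0.1`, six responses per
dose, middle dose at `x*(guess)` for guesses `{12.5, 25, 50, 75, 100}`, and
`N = 10,000` replicates. The generator emulates exactly the assumed model —
independent homoscedastic Gaussian errors around a true Emax curve at fixed
doses. It does *not* emulate heteroscedasticity, model misspecification,
dropout, or non-Gaussian tails, so passing simulation tests validate the
estimators and probabilities under the model, not robustness to its
violation. Reproducibility: each guess gets a substream seeded by
`(seed, guess_index)`; all replicates of a guess are drawn in one vectorized
call, and reruns are bit-identical.

## Numerical choices and degenerate inputs

* Pole protection: evaluating `eta` within `1e-8` of `x = -theta2` raises.
* `d_optimal_x2` requires `b > a` and `theta2 > -a`; user designs only need
  `a < x2 < b`, with a warning (CLI) when `x2` exceeds the midpoint.
* Replicate counts must be supplied as positive integers; non-integer
  `weight*n` products are never silently rounded.
* The Firth-terms determinant `D = V11*V12 - Cov12^2` is strictly positive
  for any design with two distinct weighted support points (strict
  Cauchy–Schwarz); a nonpositive `D` raises a degenerate-design error.
* Tests that compare against random-theta samples draw `theta0` from the
  data range, `theta1` uniform on `(0, 4*range]` and `theta2` log-uniform up
  to `100*b` — a falsification utility, not an exhaustive search.

## Known limitations

* Only three-point designs are classified; for more support points the
  existence geometry is an open problem and the package deliberately does
  not guess.
* No confidence intervals or standard errors; the focus is existence and
  point estimation.
* Firth success rates on Case-1 data depend mildly on the solver and
  admissibility rule; the package asserts only that they are near zero.
* The Case-2 estimate inherits Firth-root non-uniqueness in principle; the
  deterministic start order makes the reported root reproducible but a
  different solver could find a different root in pathological settings.
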