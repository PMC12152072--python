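# emaxfit

Estimation and design tools for the three-parameter **Emax dose–response
model** with Gaussian errors of known standard deviation,

```
y = eta(x, theta) + eps,     eta(x, theta) = theta0 + theta1 * x / (x + theta2),
```

on a dose range `[a, b]`. `theta0` is the placebo-level response, `theta1` the
asymptotic maximum effect and `theta2` the half-effect dose — the model's only
nonlinear parameter. The package is aimed at statisticians and trialists who
run three-point dose-finding experiments (the support of the locally
D-optimal design) and need a *finite* parameter estimate with a guarantee, or
an explanation and a remedy when none exists.

## What it does

For a three-point design `{a, x2, b}` the maximum-likelihood estimator either
exists in closed form or provably does not exist, depending only on the
geometry of the per-dose sample means `(ybar1, ybar2, ybar3)`:

* **increasing concave** (`ybar1 < ybar2 < ybar3` and chord slope `m1 > m2`):
  the MLE interpolates the three points exactly and is returned analytically;
* **Case 1** — concave but non-increasing: no MLE; the likelihood is
  dominated by a step or flat limit function; the package certifies this and
  recommends a design augmentation below the current middle dose;
* **Case 2** — convex (`m1 <= m2`): no MLE, but the root of **Firth's
  modified score equations** `U + A = 0` (with the closed-form adjustment
  `A(design, theta1, theta2)`) almost always yields a finite admissible
  estimate; the package solves them with a deterministic multi-start root
  finder.

It also computes, exactly, the probability of each of these outcomes for any
three-point design (Gaussian cone integration), the power function of the
Case-1 rejection test of `H0: theta2 >= theta2_guess`, its inversion to pick
the middle dose at a prescribed significance level, the locally D-optimal
design `{a, x*(theta2), b; 1/3, 1/3, 1/3}` with

```
x*(theta2) = (b(a+theta2) + a(b+theta2)) / ((a+theta2) + (b+theta2)),
```

and a seeded Monte-Carlo engine that reproduces all of the above empirically.

## Worked example

```python
>>> import numpy as np
>>> from emaxfit import EmaxRegressor
>>> X = np.repeat([0.0, 30.0, 150.0], 6)          # D-optimal support for theta2=50
>>> rng = np.random.default_rng(4)
>>> y = 2 + 0.467 * X / (X + 50) + rng.normal(0, 0.1, X.size)
>>> reg = EmaxRegressor(sigma=0.1).fit(X, y)
>>> reg.method_
'ANALYTIC_MLE'
>>> np.round(reg.theta_, 3)
array([ 1.997,  0.498, 54.38 ])
>>> round(reg.sse_, 6)
0.0
```

The sample means had an increasing concave shape, so the estimate is the
exact closed-form MLE: `theta0 = 1.997` (response at dose 0), maximum effect
`theta1 = 0.498`, half-effect dose `theta2 = 54.4`, and the fitted curve
passes through all three per-dose means (`sse_ = 0`). When the shape is bad,
`reg.method_` becomes `'FIRTH'` (convex data, finite modified-score estimate)
or `'LIMIT_CLASS'` (no finite estimate; `reg.limit_` holds the dominating
step/flat/line fit and a Case-1 verdict signals that the middle dose was
placed too high).

How likely is each outcome before running the experiment?

```python
>>> from emaxfit import ThreePointDesign, shape_probabilities, d_optimal_x2
>>> design = ThreePointDesign(0.001, d_optimal_x2(0.001, 150, 12.5), 150)
>>> p = shape_probabilities(design, (6, 6, 6), (2, 0.467, 50), 0.1)
>>> [round(100 * v, 2) for v in (p.p_exists, p.p_case1, p.p_case2)]
[84.82, 0.0, 15.18]
```

The same quantities are available from a shell:

```sh
emaxfit fit --data doses.csv --sigma 0.1        # JSON fit result
emaxfit design-probs --config setting.yaml      # outcome probabilities
emaxfit choose-x2 --alpha 0.05 --theta2-guess 50 --config setting.yaml
emaxfit table1 --n-replicates 10000 --seed 1 --out study.csv
```

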