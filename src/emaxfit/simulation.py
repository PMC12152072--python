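"""Seeded Monte-Carlo engine for the shape-classification study.

The study protocol: fix a dose range [a, b], a true parameter vector and a
known sigma; for each guessed theta2 place the middle dose at x*(guess);
draw n_per_point Gaussian responses per dose from the true curve; classify
the sample-mean geometry; attempt a Firth-modified solve whenever the MLE
does not exist.  Repeating N times gives observed percentages of each
outcome next to their exact theoretical twins.

Reproducibility: one root seed; each theta2 guess gets its own deterministic
substream (seeded by (seed, guess index)), so columns are independent and
the whole study reruns bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import shape_probabilities
from .firth import solve_modified_score
from .model import EmaxParams, ThreePointDesign, d_optimal_x2, eta
from .shape import SampleSummary, ShapeLabel, classify

__all__ = ["StudyConfig", "StudyResult", "simulate_replicate", "run_study"]


@dataclass(frozen=True)
class StudyConfig:
    """Protocol of a simulation study.

    Defaults are the reference setting used throughout the package:
    a=0.001, b=150, true theta=(2, 0.467, 50), sigma=0.1, six responses
    per dose, guesses {12.5, 25, 50, 75, 100}, N=10,000 replicates.
    """

    a: float = 0.001
    b: float = 150.0
    theta_true: tuple = (2.0, 0.467, 50.0)
    sigma: float = 0.1
    n_per_point: int = 6
    theta2_guesses: tuple = (12.5, 25.0, 50.0, 75.0, 100.0)
    n_replicates: int = 10_000
    seed: int = 0

    def __post_init__(self):
        if self.n_replicates < 1 or self.n_per_point < 1:
            raise ValueError("n_replicates and n_per_point must be >= 1")
        EmaxParams.from_array(self.theta_true).validate(self.a)
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")

    def design_for(self, theta2_guess: float) -> ThreePointDesign:
        return ThreePointDesign(self.a, d_optimal_x2(self.a, self.b, theta2_guess), self.b)


@dataclass(frozen=True)
class StudyResult:
    """Observed and theoretical percentages per theta2 guess.

    ``table`` columns: theta2_guess, pct_exists, th_exists, pct_case1,
    th_case1, firth_case1, pct_case2, th_case2, firth_case2, n_replicates,
    seed.  Firth columns are percentages among the replicates of that case
    (NaN when the case never occurred).  ``labels`` maps each guess to the
    per-replicate shape labels.
    """

    table: pd.DataFrame
    labels: dict
    config: StudyConfig

    def to_csv(self, path):
        self.table.to_csv(path, index=False)


def simulate_replicate(
    config: StudyConfig, theta2_guess: float, rng: np.random.Generator
) -> SampleSummary:
    """One replicate: n_per_point responses per dose from the true curve."""
    design = config.design_for(theta2_guess)
    mu = eta(design.support, config.theta_true)
    y = mu[:, None] + config.sigma * rng.standard_normal((3, config.n_per_point))
    return SampleSummary(
        design,
        (config.n_per_point,) * 3,
        tuple(float(m) for m in y.mean(axis=1)),
        config.sigma if config.sigma > 0 else 1.0,
    )


def _classify_batch(x: np.ndarray, ybar: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Vectorized shape labels for an (N, 3) array of sample means."""
    m1 = (ybar[:, 1] - ybar[:, 0]) / (x[1] - x[0])
    m2 = (ybar[:, 2] - ybar[:, 0]) / (x[2] - x[0])
    y23 = (n[1] * ybar[:, 1] + n[2] * ybar[:, 2]) / (n[1] + n[2])
    w = n / n.sum()
    xm = np.sum(w * x)
    ym = ybar @ w
    sxx = np.sum(w * (x - xm) ** 2)
    m0 = (ybar - ym[:, None]) @ (w * (x - xm)) / sxx
    concave = m1 > m2
    increasing = (ybar[:, 0] < ybar[:, 1]) & (ybar[:, 1] < ybar[:, 2])
    labels = np.empty(len(ybar), dtype=object)
    labels[concave & increasing] = ShapeLabel.INCREASING_CONCAVE
    c1 = concave & ~increasing
    labels[c1 & (ybar[:, 0] < y23)] = ShapeLabel.CASE1_Y1_BELOW
    labels[c1 & (ybar[:, 0] >= y23)] = ShapeLabel.CASE1_Y1_ABOVE
    labels[~concave & (m0 > 0)] = ShapeLabel.CASE2_POS_SLOPE
    labels[~concave & (m0 <= 0)] = ShapeLabel.CASE2_NONPOS_SLOPE
    return labels


def run_study(config: StudyConfig, firth: bool = True) -> StudyResult:
    """Run the full Monte-Carlo study.

    For each guess: simulate N replicates, classify each, attempt a Firth
    solve on every Case-1 and Case-2 replicate (solver failures are tallied,
    never raised), and tabulate observed percentages beside the exact
    theoretical probabilities.
    """
    rows = []
    labels_by_guess = {}
    N = config.n_replicates
    npp = config.n_per_point
    for gi, guess in enumerate(config.theta2_guesses):
        design = config.design_for(guess)
        x = design.support
        counts = np.array([npp] * 3, dtype=float)
        mu = eta(x, config.theta_true)
        rng = np.random.default_rng([config.seed, gi])
        y = mu[None, :, None] + config.sigma * rng.standard_normal((N, 3, npp))
        ybar = y.mean(axis=2)
        labels = _classify_batch(x, ybar, counts)
        labels_by_guess[guess] = labels
        is_c1 = np.array([lab.is_case1 for lab in labels])
        is_c2 = np.array([lab.is_case2 for lab in labels])
        n_exists = int(np.sum(~is_c1 & ~is_c2))
        firth_ok = {True: 0, False: 0}  # keyed by is_case1
        if firth:
            for i in np.nonzero(is_c1 | is_c2)[0]:
                summary = SampleSummary(
                    design,
                    (npp,) * 3,
                    tuple(ybar[i]),
                    config.sigma if config.sigma > 0 else 1.0,
                )
                sol = solve_modified_score(summary)
                if sol.admissible:
                    firth_ok[bool(is_c1[i])] += 1
        n_c1, n_c2 = int(is_c1.sum()), int(is_c2.sum())
        theo = shape_probabilities(design, counts, config.theta_true, config.sigma) \
            if config.sigma > 0 else None
        rows.append(
            {
                "theta2_guess": guess,
                "pct_exists": 100 * n_exists / N,
                "th_exists": 100 * theo.p_exists if theo else np.nan,
                "pct_case1": 100 * n_c1 / N,
                "th_case1": 100 * theo.p_case1 if theo else np.nan,
                "firth_case1": 100 * firth_ok[True] / n_c1 if n_c1 else np.nan,
                "pct_case2": 100 * n_c2 / N,
                "th_case2": 100 * theo.p_case2 if theo else np.nan,
                "firth_case2": 100 * firth_ok[False] / n_c2 if n_c2 else np.nan,
                "n_replicates": N,
                "seed": config.seed,
            }
        )
    return StudyResult(pd.DataFrame(rows), labels_by_guess, config)
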