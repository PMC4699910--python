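"""Maximum-likelihood power-law fitting of step lengths and walk classification.

Above some minimum step length x_min the tail of a Levy walk's
step-length distribution follows a continuous power law

    p(S) = (alpha - 1) / x_min * (S / x_min)^(-alpha),

whose exponent has the closed-form maximum-likelihood estimate (Hill
estimator)

    alpha_hat = 1 + n * [ sum_j ln(S_j / x_min) ]^(-1)

over the n tail values S_j >= x_min.  x_min itself is chosen by the
Clauset-Shalizi-Newman procedure: every distinct observed value is a
candidate, the tail above each candidate is fitted, and the candidate
minimizing the Kolmogorov-Smirnov distance D between the empirical tail
CDF and the fitted model CDF wins (ties go to the smaller candidate — the
larger tail has more statistical power).

The exponent classifies the walk:

    alpha <= 1        ballistic   (not normalizable as a power law)
    1 < alpha <= 3    Levy flight (divergent variance)
    alpha > 3         Brownian    (effectively finite-variance steps)
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
import json

import numpy as np
import pandas as pd

from .steps import StepSeries

__all__ = [
    "DivergentFitError",
    "InsufficientDataError",
    "PowerLawFit",
    "mle_alpha",
    "ks_distance",
    "estimate_xmin",
    "classify_walk",
    "fit_steps",
    "fit_values",
    "ccdf_table",
]

BALLISTIC = "ballistic"
LEVY = "levy"
BROWNIAN = "brownian"


class DivergentFitError(ValueError):
    """All tail values equal x_min: the likelihood has no finite maximum."""


class InsufficientDataError(ValueError):
    """Too few positive step lengths to attempt a tail fit."""


@dataclass
class PowerLawFit:
    """Result of a truncated power-law tail fit on a step-length sample."""

    alpha: float
    xmin: float
    ks_distance: float
    n_tail: int
    n_total: int
    min_step: float
    max_step: float
    walk_class: str

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def summary_row(self, length_min: float | None = None) -> pd.DataFrame:
        """One-row table in the conventional fit-report column order."""
        return pd.DataFrame(
            [
                {
                    "length_min": length_min,
                    "n_step": self.n_total,
                    "min_step": self.min_step,
                    "max_step": self.max_step,
                    "est_xmin": self.xmin,
                    "n_tail": self.n_tail,
                    "est_alpha": self.alpha,
                    "distance": self.ks_distance,
                    "walk_class": self.walk_class,
                }
            ]
        )


def _clean(values) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    return v[np.isfinite(v) & (v > 0)]


def mle_alpha(tail, xmin: float) -> float:
    """Closed-form MLE of the power-law exponent on values >= xmin.

    alpha_hat = 1 + n / sum(ln(S_j / xmin)).  Raises
    :class:`DivergentFitError` when every value equals xmin (the log-sum
    vanishes and the estimate diverges).
    """
    if xmin <= 0:
        raise ValueError("xmin must be positive")
    v = np.asarray(tail, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 tail values")
    if np.any(v < xmin * (1 - 1e-12)):
        raise ValueError("all tail values must be >= xmin")
    s = float(np.sum(np.log(v / xmin)))
    if s <= 0.0:
        raise DivergentFitError("all tail values equal xmin; MLE diverges")
    return 1.0 + v.size / s


def ks_distance(tail, xmin: float, alpha: float) -> float:
    """KS distance between the empirical tail CDF and the fitted model CDF.

    Model CDF (continuous power law): F(x) = 1 - (x/xmin)^(1-alpha).
    The empirical CDF is compared on both sides of each jump.
    """
    v = np.sort(np.asarray(tail, dtype=float))
    n = v.size
    if n == 0:
        raise ValueError("empty tail")
    model = 1.0 - (v / xmin) ** (1.0 - alpha)
    hi = np.arange(1, n + 1) / n
    lo = np.arange(0, n) / n
    return float(np.max(np.maximum(np.abs(hi - model), np.abs(lo - model))))


def estimate_xmin(
    steps: StepSeries | np.ndarray,
    tail_floor: int = 10,
) -> tuple[float, float, int]:
    """Choose x_min by minimizing the KS distance over observed candidates.

    Candidates are the distinct observed (positive) step values whose tail
    retains at least ``tail_floor`` points.  Returns
    ``(xmin, ks_distance, n_tail)``.  Raises
    :class:`InsufficientDataError` below the floor and
    :class:`DivergentFitError` when no candidate admits a finite fit
    (e.g. all values identical).
    """
    values = steps.lengths if isinstance(steps, StepSeries) else steps
    v = np.sort(_clean(values))
    if v.size < tail_floor:
        raise InsufficientDataError(
            f"need at least {tail_floor} positive step lengths, got {v.size}"
        )
    candidates = np.unique(v)
    best: tuple[float, float, int] | None = None
    for c in candidates:
        tail = v[v >= c]
        if tail.size < tail_floor:
            break  # candidates are ascending; tails only shrink
        try:
            a = mle_alpha(tail, float(c))
        except DivergentFitError:
            continue
        d = ks_distance(tail, float(c), a)
        if best is None or d < best[1]:  # strict <: ties keep the smaller xmin
            best = (float(c), d, tail.size)
    if best is None:
        raise DivergentFitError("no candidate xmin admits a finite power-law fit")
    return best


def classify_walk(alpha: float) -> str:
    """Partition the exponent line: <=1 ballistic, (1, 3] Levy, >3 Brownian."""
    if not np.isfinite(alpha):
        raise ValueError("alpha must be finite")
    if alpha <= 1.0:
        return BALLISTIC
    if alpha <= 3.0:
        return LEVY
    return BROWNIAN


def fit_values(
    values,
    xmin: float | None = None,
    tail_floor: int = 10,
) -> PowerLawFit:
    """Full tail fit of a raw step-length sample.

    With ``xmin`` given, estimation is skipped and the tail above it is
    fitted directly (fixed-xmin mode).
    """
    v = _clean(values)
    if v.size < tail_floor:
        raise InsufficientDataError(
            f"need at least {tail_floor} positive step lengths, got {v.size}"
        )
    if xmin is None:
        xm, d, n_tail = estimate_xmin(v, tail_floor=tail_floor)
        alpha = mle_alpha(v[v >= xm], xm)
    else:
        if xmin <= 0:
            raise ValueError("xmin must be positive")
        tail = v[v >= xmin]
        if tail.size < 2:
            raise InsufficientDataError("fewer than 2 values above the given xmin")
        xm = float(xmin)
        alpha = mle_alpha(tail, xm)
        d = ks_distance(tail, xm, alpha)
        n_tail = tail.size
    return PowerLawFit(
        alpha=float(alpha),
        xmin=float(xm),
        ks_distance=float(d),
        n_tail=int(n_tail),
        n_total=int(v.size),
        min_step=float(v.min()),
        max_step=float(v.max()),
        walk_class=classify_walk(alpha),
    )


def fit_steps(
    steps: StepSeries,
    xmin: float | None = None,
    tail_floor: int = 10,
    window_minutes: float | None = None,
) -> PowerLawFit:
    """Fit the step-length tail of a :class:`StepSeries`.

    ``window_minutes`` restricts the fit to steps whose terminating event
    falls within the first so-many minutes of the recording (analysis
    window); None uses the whole series.
    """
    lengths = steps.lengths
    if window_minutes is not None and len(steps):
        t0 = float(steps.t_start.min())
        lengths = lengths[steps.t_end <= t0 + window_minutes * 60.0]
    return fit_values(lengths, xmin=xmin, tail_floor=tail_floor)


def ccdf_table(values, fit: PowerLawFit) -> pd.DataFrame:
    """Empirical and fitted-model CCDFs over the tail, aligned at x_min.

    Suitable for log-log plotting: the empirical CCDF starts at 1 at the
    smallest tail value and is nonincreasing; the model CCDF is
    (x/xmin)^(1-alpha), exactly 1 at x = xmin.
    """
    v = np.sort(_clean(values))
    tail = v[v >= fit.xmin]
    if tail.size == 0:
        raise ValueError("no values above xmin")
    n = tail.size
    empirical = 1.0 - np.arange(n) / n  # P(X >= x) just left of each point
    model = (tail / fit.xmin) ** (1.0 - fit.alpha)
    return pd.DataFrame({"x": tail, "empirical_ccdf": empirical, "model_ccdf": model})
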