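"""Unequal-variance signal detection core.

Two-choice decisions are modelled as criteria applied to a scalar evidence
sample drawn from one of two Gaussian classes.  The "low" class is the
low-variance stimulus category (anticlockwise / absent / vertical) and the
"high" class the high-variance one (clockwise / present / tilted).  A
6-level confidence scale folds into a 12-point rating axis:
(respond low, confidence 6..1) then (respond high, confidence 1..6),
carved out of the evidence axis by 11 strictly increasing criteria whose
middle element is the decision criterion.

The module provides the log-likelihood ratio of a sample, a rating-table
simulator, the geometric-mean type-1 zROC slope estimator (which converges
to sigma_low / sigma_high for Gaussian classes), the response-conditional
type-2 ROC area (metacognitive sensitivity), and the ideal-observer
probability of giving the low-variance response.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "UVSDTParams",
    "RatingCountTable",
    "MetacogSummary",
    "llr",
    "simulate_ratings",
    "zroc_slope",
    "auroc2",
    "predicted_low_response_rate",
]


@dataclass(frozen=True)
class UVSDTParams:
    """Two-Gaussian evidence model plus rating policy.

    ``criteria`` holds the ``2 * n_conf_levels - 1`` rating criteria on the
    evidence axis (11 for a 6-level scale).  When omitted they are placed at
    the quantiles of the stimulus mixture so that all rating bins are
    populated in expectation.
    """

    mu_low: float = 0.0
    sigma_low: float = 1.0
    mu_high: float = 1.0
    sigma_high: float = 1.0
    prior_high: float = 0.5
    n_conf_levels: int = 6
    criteria: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not (self.sigma_low > 0 and self.sigma_high > 0):
            raise ValueError("sigma_low and sigma_high must be positive")
        if not 0.0 < self.prior_high < 1.0:
            raise ValueError("prior_high must lie in (0, 1)")
        if self.n_conf_levels < 2:
            raise ValueError("n_conf_levels must be >= 2")
        if self.criteria is None:
            object.__setattr__(
                self, "criteria", tuple(_mixture_quantile_criteria(self))
            )
        else:
            crit = tuple(float(c) for c in self.criteria)
            if len(crit) != 2 * self.n_conf_levels - 1:
                raise ValueError(
                    f"expected {2 * self.n_conf_levels - 1} criteria, got {len(crit)}"
                )
            if not np.all(np.diff(crit) > 0):
                raise ValueError("criteria must be strictly increasing")
            object.__setattr__(self, "criteria", crit)

    @property
    def n_bins(self) -> int:
        return 2 * self.n_conf_levels

    @property
    def decision_criterion(self) -> float:
        """Middle criterion: evidence above it yields the 'high' response."""
        return self.criteria[self.n_conf_levels - 1]

    def with_separation_gain(self, gain: float) -> "UVSDTParams":
        """Scale the mean separation by ``gain`` keeping the low class fixed.

        Used by the session simulator, where stimulus strength (visibility or
        orientation spread) maps onto evidence separation.  Criteria are kept
        as-is: they belong to the observer, not the stimulus.
        """
        mu_high = self.mu_low + gain * (self.mu_high - self.mu_low)
        return replace(self, mu_high=mu_high, criteria=self.criteria)


def _mixture_cdf(x: float, p: UVSDTParams) -> float:
    lo = stats.norm.cdf(x, p.mu_low, p.sigma_low)
    hi = stats.norm.cdf(x, p.mu_high, p.sigma_high)
    return (1.0 - p.prior_high) * lo + p.prior_high * hi


def _mixture_quantile_criteria(p: UVSDTParams) -> list[float]:
    """Default rating criteria.

    The decision criterion sits at the ideal-observer boundary (the
    increasing crossing of the log-likelihood ratio with the log prior
    odds), which for unequal variances lies above the mixture median and
    reproduces the empirical preference for the low-variance response.  The
    five confidence criteria on each side are quantiles of the stimulus
    mixture conditional on that side, so every rating bin is populated in
    expectation.
    """
    lo = min(p.mu_low - 8 * p.sigma_low, p.mu_high - 8 * p.sigma_high)
    hi = max(p.mu_low + 8 * p.sigma_low, p.mu_high + 8 * p.sigma_high)
    thr = np.log((1.0 - p.prior_high) / p.prior_high)

    def g(x):
        return (
            stats.norm.logpdf(x, p.mu_high, p.sigma_high)
            - stats.norm.logpdf(x, p.mu_low, p.sigma_low)
            - thr
        )

    # increasing root of the (at most quadratic) llr; bracket from the left
    # edge of the high-density region upwards
    mid = (p.mu_low + p.mu_high) / 2
    x0 = mid
    span = max(p.sigma_low, p.sigma_high)
    while g(x0) > 0 and x0 > lo:
        x0 -= span
    x1 = x0
    while g(x1) < 0 and x1 < hi:
        x1 += span
    c_mid = optimize.brentq(g, x0, x1) if g(x0) < 0 < g(x1) else mid
    f_mid = _mixture_cdf(c_mid, p)
    n = p.n_conf_levels
    out = []
    for k in range(1, n):  # below the decision criterion
        q = f_mid * k / n
        out.append(optimize.brentq(lambda x: _mixture_cdf(x, p) - q, lo, c_mid))
    out.append(c_mid)
    for k in range(1, n):  # above
        q = f_mid + (1 - f_mid) * k / n
        out.append(optimize.brentq(lambda x: _mixture_cdf(x, p) - q, c_mid, hi))
    return out


@dataclass(frozen=True)
class RatingCountTable:
    """Counts on the folded 12-point rating scale, one row per true class.

    Bin order along the evidence axis: (respond low, conf 6..1) then
    (respond high, conf 1..6), i.e. bin 0 is the most confident
    low-variance-class response.
    """

    counts: np.ndarray  # shape (2, n_bins); row 0 = low class, row 1 = high
    n_conf_levels: int = 6

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (2, 2 * self.n_conf_levels):
            raise ValueError(
                f"counts must have shape (2, {2 * self.n_conf_levels})"
            )
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    def swap_classes(self) -> "RatingCountTable":
        """Relabel classes: swap rows and reverse the rating axis."""
        return RatingCountTable(self.counts[::-1, ::-1], self.n_conf_levels)

    def to_tsv(self, path) -> None:
        n = self.n_conf_levels
        header = [f"low_c{c}" for c in range(n, 0, -1)] + [
            f"high_c{c}" for c in range(1, n + 1)
        ]
        with open(path, "w") as fh:
            fh.write("class\t" + "\t".join(header) + "\n")
            for name, row in zip(("low", "high"), self.counts):
                fh.write(name + "\t" + "\t".join(str(int(v)) for v in row) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "RatingCountTable":
        with open(path) as fh:
            header = fh.readline().split("\t")
            rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
        n_bins = len(header) - 1
        counts = np.array([[int(v) for v in row[1:]] for row in rows])
        return cls(counts, n_conf_levels=n_bins // 2)


@dataclass(frozen=True)
class MetacogSummary:
    """Behavioural summary for one task."""

    zroc_slope: float
    auroc2_by_response: tuple[float, float]  # (low response, high response)
    accuracy: float
    response_rate_low: float
    mean_confidence_by_response: tuple[float, float]
    n_trials: int = 0


def llr(x, params: UVSDTParams):
    """Log-likelihood ratio log N(x; high) - log N(x; low).

    Linear in ``x`` exactly when the class variances are equal, quadratic
    otherwise (even in ``x`` when the means coincide).
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("evidence sample must be finite")
    out = stats.norm.logpdf(x, params.mu_high, params.sigma_high) - stats.norm.logpdf(
        x, params.mu_low, params.sigma_low
    )
    return out if out.ndim else float(out)


def llr_coefficients(params: UVSDTParams) -> tuple[float, float, float]:
    """Coefficients (a, b, c) of llr(x) = a x^2 + b x + c."""
    sl2 = params.sigma_low**2
    sh2 = params.sigma_high**2
    a = 0.5 / sl2 - 0.5 / sh2
    b = params.mu_high / sh2 - params.mu_low / sl2
    c = (
        params.mu_low**2 / (2 * sl2)
        - params.mu_high**2 / (2 * sh2)
        + np.log(params.sigma_low / params.sigma_high)
    )
    return a, b, c


def simulate_ratings(
    params: UVSDTParams, n_per_class: int, seed: int | np.random.Generator
) -> RatingCountTable:
    """Draw ``n_per_class`` evidence samples per class and bin by criteria."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    crit = np.asarray(params.criteria)
    if not np.all(np.diff(crit) > 0):
        raise ValueError("criteria must be strictly increasing")
    rng = np.random.default_rng(seed)
    counts = np.zeros((2, params.n_bins), dtype=np.int64)
    for row, (mu, sigma) in enumerate(
        [(params.mu_low, params.sigma_low), (params.mu_high, params.sigma_high)]
    ):
        x = rng.normal(mu, sigma, size=n_per_class)
        bins = np.searchsorted(crit, x)
        counts[row] = np.bincount(bins, minlength=params.n_bins)
    return RatingCountTable(counts, params.n_conf_levels)


def rating_bin(response_is_high: bool, confidence: int, n_conf_levels: int = 6) -> int:
    """Index on the folded rating axis for a (response, confidence) pair."""
    if not 1 <= confidence <= n_conf_levels:
        raise ValueError("confidence out of range")
    if response_is_high:
        return n_conf_levels + confidence - 1
    return n_conf_levels - confidence


def zroc_slope(table: RatingCountTable) -> float:
    """Geometric-mean type-1 zROC slope.

    Cumulative 'high-side' proportions are formed at each of the interior
    criteria for both classes, z-transformed, and a slope estimated in both
    regression directions (z_hit on z_fa, and the reciprocal of z_fa on
    z_hit); the returned value is the geometric mean of the two.  A 0.5
    log-linear correction is added to every cumulative cell so that empty
    extremes stay usable.  For large Gaussian samples this converges to
    sigma_low / sigma_high.
    """
    counts = table.counts
    if (counts.sum(axis=1) == 0).any():
        raise ValueError("each class needs at least one trial")
    if any(np.count_nonzero(row) < 2 for row in counts):
        raise ValueError("degenerate table: a class has all mass in one bin")
    n_crit = counts.shape[1] - 1
    totals = counts.sum(axis=1, keepdims=True)
    # counts above criterion k, for k = 1..n_crit
    above = np.cumsum(counts[:, ::-1], axis=1)[:, ::-1][:, 1:]
    prop = (above + 0.5) / (totals + 1.0)
    z = stats.norm.ppf(prop)
    z_fa, z_hit = z[0], z[1]
    if len(z_fa) < 2:
        raise ValueError("need at least 2 usable criteria")
    s1 = np.polyfit(z_fa, z_hit, 1)[0]
    s2_inv = np.polyfit(z_hit, z_fa, 1)[0]
    if s1 <= 0 or s2_inv <= 0:
        raise ValueError("non-positive zROC slope; table too degenerate")
    return float(np.sqrt(s1 / s2_inv))


def auroc2(correct_counts: Sequence[float], error_counts: Sequence[float]) -> float:
    """Area under the response-conditional type-2 ROC curve.

    ``correct_counts[k]`` / ``error_counts[k]`` are the numbers of correct /
    incorrect trials rated at confidence level ``k+1``.  The curve plots the
    cumulative p(conf >= k | correct) against p(conf >= k | error), anchored
    at (0, 0); (1, 1) is reached at the lowest level.
    """
    c = np.asarray(correct_counts, dtype=float)
    e = np.asarray(error_counts, dtype=float)
    if c.shape != e.shape or c.ndim != 1:
        raise ValueError("count sequences must be 1-d and equal length")
    if (c < 0).any() or (e < 0).any():
        raise ValueError("counts must be non-negative")
    if c.sum() <= 0 or e.sum() <= 0:
        raise ValueError("each sequence needs a positive total")
    # cumulative from the top confidence level down
    y = np.concatenate([[0.0], np.cumsum(c[::-1]) / c.sum()])
    x = np.concatenate([[0.0], np.cumsum(e[::-1]) / e.sum()])
    return float(np.trapezoid(y, x))


def recover_group_zroc_slope(
    sigma_high: float,
    n_observers: int = 35,
    n_per_class: int = 1000,
    n_seeds: int = 20,
    seed: int = 0,
    mu_high: float = 1.0,
) -> float:
    """Group geometric-mean zROC slope recovered from simulated cohorts.

    Each observer rates ``2 * n_per_class`` trials from classes N(0, 1) and
    N(mu_high, sigma_high) on the 6-level confidence scale; the group value
    exponentiates the mean of log slopes over observers (a geometric mean),
    and the result averages ``n_seeds`` independent cohorts.
    """
    params = UVSDTParams(
        mu_low=0.0, sigma_low=1.0, mu_high=mu_high, sigma_high=sigma_high
    )
    ss = np.random.SeedSequence([seed, 823])
    group_values = []
    for cohort in ss.spawn(n_seeds):
        rng = np.random.default_rng(cohort)
        logs = [
            np.log(zroc_slope(simulate_ratings(params, n_per_class, rng)))
            for _ in range(n_observers)
        ]
        group_values.append(np.exp(np.mean(logs)))
    return float(np.mean(group_values))


def predicted_low_response_rate(params: UVSDTParams) -> float:
    """Probability that an ideal observer gives the low-variance response.

    The observer responds 'high' when the posterior favours the high class,
    i.e. when llr(x) exceeds the log prior odds against it.  The response
    region is resolved analytically from the quadratic llr and integrated
    against the stimulus mixture.  For equal priors and sigma_high >
    sigma_low the optimal criterion placement yields a rate above 0.5.
    """
    a, b, c = llr_coefficients(params)
    thr = np.log((1.0 - params.prior_high) / params.prior_high)
    c = c - thr
    # solve a x^2 + b x + c < 0  -> "low" region
    if abs(a) < 1e-14:
        if abs(b) < 1e-14:
            return 1.0 if c < 0 else 0.0
        x0 = -c / b
        intervals = [(-np.inf, x0)] if b > 0 else [(x0, np.inf)]
    else:
        disc = b * b - 4 * a * c
        if disc <= 0:
            intervals = [] if a > 0 else [(-np.inf, np.inf)]
        else:
            r1 = (-b - np.sqrt(disc)) / (2 * a)
            r2 = (-b + np.sqrt(disc)) / (2 * a)
            lo, hi = min(r1, r2), max(r1, r2)
            if a > 0:
                intervals = [(lo, hi)]
            else:
                intervals = [(-np.inf, lo), (hi, np.inf)]
    p = 0.0
    for lo, hi in intervals:
        for prior, mu, sigma in (
            (1.0 - params.prior_high, params.mu_low, params.sigma_low),
            (params.prior_high, params.mu_high, params.sigma_high),
        ):
            p += prior * (
                stats.norm.cdf(hi, mu, sigma) - stats.norm.cdf(lo, mu, sigma)
            )
    return float(p)
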