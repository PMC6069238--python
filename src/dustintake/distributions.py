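"""Lognormal distribution fitting and algebra.

Every input variable of the intake model (ingestion rate, concentration,
body weight) is carried as a :class:`LognormalSpec` — the log-space location
``mu`` and scale ``sigma`` of a lognormal law.  Three fitting routes cover the
three kinds of published evidence such variables come with:

* arithmetic mean/SD pairs  → :func:`fit_from_moments` (moment matching),
* percentile tables         → :func:`fit_from_percentiles` (probit regression),
* left-censored raw samples → :func:`fit_from_censored` (half-LOD substitution
  followed by moment matching).

Because products and quotients of independent lognormals are again lognormal,
:func:`combine_product_quotient` gives the exact distribution of the intake
equation and serves as the closed-form oracle against which the Monte Carlo
engine is validated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .errors import (
    DataError,
    InsufficientDataError,
    InvalidCompositionError,
    InvalidLODError,
    InvalidSummaryError,
    InvalidTableError,
)

__all__ = [
    "LognormalSpec",
    "SummaryMoments",
    "PercentileTable",
    "CensoredSample",
    "fit_from_moments",
    "fit_from_percentiles",
    "substitute_half_lod",
    "fit_from_censored",
    "lognormal_quantile",
    "combine_product_quotient",
    "rsd",
    "compare_fit_to_percentiles",
]


@dataclass(frozen=True)
class LognormalSpec:
    """Lognormal law in log-space parameters.

    ``mu`` is the natural log of the median (in the variable's unit), ``sigma``
    the dimensionless log-space SD.  ``sigma`` must be strictly positive; a
    degenerate point mass is built only through :meth:`point_mass`.
    """

    mu: float
    sigma: float
    unit_label: str = ""

    def __post_init__(self) -> None:
        if not math.isfinite(self.mu):
            raise DataError(f"mu must be finite, got {self.mu!r}")
        if not (math.isfinite(self.sigma) and self.sigma > 0):
            raise DataError(
                f"sigma must be > 0, got {self.sigma!r}; "
                "use LognormalSpec.point_mass for a degenerate distribution"
            )

    @classmethod
    def point_mass(cls, value: float, unit_label: str = "") -> "LognormalSpec":
        """Degenerate distribution concentrated at ``value`` (> 0)."""
        if not (math.isfinite(value) and value > 0):
            raise DataError(f"point mass requires a positive value, got {value!r}")
        self = object.__new__(cls)
        object.__setattr__(self, "mu", math.log(value))
        object.__setattr__(self, "sigma", 0.0)
        object.__setattr__(self, "unit_label", unit_label)
        return self

    @property
    def is_point_mass(self) -> bool:
        return self.sigma == 0.0

    @property
    def mean(self) -> float:
        """Arithmetic mean exp(mu + sigma^2/2)."""
        return math.exp(self.mu + self.sigma**2 / 2.0)

    @property
    def sd(self) -> float:
        """Arithmetic standard deviation."""
        return self.mean * math.sqrt(math.expm1(self.sigma**2))

    @property
    def median(self) -> float:
        return math.exp(self.mu)

    def quantile(self, p):
        return lognormal_quantile(self, p)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` variates; a point mass still consumes ``n`` normals so
        parallel streams stay aligned across degenerate/non-degenerate specs."""
        z = rng.standard_normal(n)
        return np.exp(self.mu + self.sigma * z)


@dataclass(frozen=True)
class SummaryMoments:
    """Published arithmetic mean/SD (and optionally N) of a variable."""

    mean: float
    sd: float
    n: int | None = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.mean) and self.mean > 0):
            raise InvalidSummaryError(f"mean must be > 0, got {self.mean!r}")
        if not (math.isfinite(self.sd) and self.sd >= 0):
            raise InvalidSummaryError(f"sd must be >= 0, got {self.sd!r}")
        if self.n is not None and self.n < 1:
            raise InvalidSummaryError(f"n must be a positive integer, got {self.n!r}")


@dataclass(frozen=True)
class PercentileTable:
    """Ordered (probability, value) pairs, e.g. a growth-chart row."""

    entries: tuple[tuple[float, float], ...]

    def __init__(self, entries: Sequence[tuple[float, float]]):
        object.__setattr__(self, "entries", tuple((float(p), float(v)) for p, v in entries))
        probs = [p for p, _ in self.entries]
        vals = [v for _, v in self.entries]
        if any(not (0.0 < p < 1.0) for p in probs):
            raise InvalidTableError("probabilities must lie strictly inside (0, 1)")
        if any(p2 <= p1 for p1, p2 in zip(probs, probs[1:])):
            raise InvalidTableError("probabilities must be strictly increasing")
        if any(v2 < v1 for v1, v2 in zip(vals, vals[1:])):
            raise InvalidTableError("values must be non-decreasing")

    @property
    def probabilities(self) -> np.ndarray:
        return np.array([p for p, _ in self.entries])

    @property
    def values(self) -> np.ndarray:
        return np.array([v for _, v in self.entries])

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class CensoredSample:
    """Raw concentrations with below-detection flags and the assay LOD.

    ``values[i]`` is the measured (or, for censored entries, internally
    retained) concentration; ``censored[i]`` is True where the assay reported
    a value below ``lod``.
    """

    values: tuple[float, ...]
    censored: tuple[bool, ...]
    lod: float

    def __init__(self, values: Sequence[float], censored: Sequence[bool], lod: float):
        object.__setattr__(self, "values", tuple(float(v) for v in values))
        object.__setattr__(self, "censored", tuple(bool(c) for c in censored))
        object.__setattr__(self, "lod", float(lod))
        if len(self.values) != len(self.censored):
            raise DataError("values and censored flags must have equal length")
        if not (math.isfinite(self.lod) and self.lod > 0):
            raise InvalidLODError(f"LOD must be > 0, got {lod!r}")
        if any(v < 0 for v, c in zip(self.values, self.censored) if not c):
            raise DataError("uncensored concentrations must be >= 0")

    def __len__(self) -> int:
        return len(self.values)


def fit_from_moments(summary: SummaryMoments, unit_label: str = "") -> LognormalSpec:
    """Moment-match a lognormal to an arithmetic mean/SD pair.

    Uses the closed forms ``sigma^2 = ln(1 + (sd/mean)^2)`` and
    ``mu = ln(mean) - sigma^2/2``, so the fitted law reproduces the input
    moments exactly.  ``sd == 0`` degenerates to a point mass at the mean.
    """
    if summary.sd == 0.0:
        return LognormalSpec.point_mass(summary.mean, unit_label)
    cv2 = (summary.sd / summary.mean) ** 2
    sigma = math.sqrt(math.log1p(cv2))
    mu = math.log(summary.mean) - sigma**2 / 2.0
    return LognormalSpec(mu=mu, sigma=sigma, unit_label=unit_label)


def fit_from_percentiles(table: PercentileTable, unit_label: str = "") -> LognormalSpec:
    """Fit a lognormal to a percentile table by probit regression.

    Ordinary least squares of ``ln(value)`` on the standard-normal quantile of
    the probability: the slope is ``sigma``, the intercept ``mu``.  With
    exactly two entries the fit interpolates them exactly.
    """
    if len(table) < 2:
        raise InsufficientDataError("need at least 2 percentile entries to fit")
    vals = table.values
    if np.any(vals <= 0):
        raise DataError("percentile values must be strictly positive for a lognormal fit")
    z = norm.ppf(table.probabilities)
    sigma, mu = np.polyfit(z, np.log(vals), 1)
    if abs(sigma) < 1e-12:  # constant table up to rounding
        sigma = 0.0
    if sigma == 0.0:
        return LognormalSpec.point_mass(float(np.exp(mu)), unit_label)
    return LognormalSpec(mu=float(mu), sigma=float(sigma), unit_label=unit_label)


def substitute_half_lod(sample: CensoredSample) -> list[float]:
    """Replace every below-detection value by LOD/2; leave the rest alone."""
    half = sample.lod / 2.0
    return [half if c else v for v, c in zip(sample.values, sample.censored)]


def fit_from_censored(sample: CensoredSample, unit_label: str = "") -> LognormalSpec:
    """Half-LOD substitution followed by moment matching on the sample mean/SD.

    Mirrors the field convention for left-censored assay data: censored
    entries become LOD/2, then the substituted sample's arithmetic mean and
    (population, ddof=1) SD are moment-matched.  An all-equal substituted
    sample yields a point mass.
    """
    if len(sample) < 3:
        raise InsufficientDataError(f"need >= 3 observations, got {len(sample)}")
    subst = np.asarray(substitute_half_lod(sample))
    mean = float(subst.mean())
    sd = float(subst.std(ddof=1))
    if sd <= 1e-12 * mean:  # all-equal sample up to rounding
        sd = 0.0
    return fit_from_moments(SummaryMoments(mean=mean, sd=sd, n=len(sample)), unit_label)


def lognormal_quantile(spec: LognormalSpec, p):
    """Quantile function exp(mu + sigma * z_p); vectorized over ``p``."""
    p_arr = np.asarray(p, dtype=float)
    if np.any((p_arr <= 0.0) | (p_arr >= 1.0)):
        raise DataError("probability must lie strictly inside (0, 1)")
    out = np.exp(spec.mu + spec.sigma * norm.ppf(p_arr))
    return float(out) if np.isscalar(p) or p_arr.ndim == 0 else out


def combine_product_quotient(
    numerators: Sequence[LognormalSpec],
    denominators: Sequence[LognormalSpec] = (),
    scale: float = 1.0,
    unit_label: str = "",
) -> LognormalSpec:
    """Exact law of ``scale * prod(numerators) / prod(denominators)``.

    For independent lognormals the log-space parameters add:
    ``mu = sum(mu_num) - sum(mu_den) + ln(scale)`` and
    ``sigma = sqrt(sum(sigma_num^2) + sum(sigma_den^2))``.
    """
    if len(numerators) == 0:
        raise InvalidCompositionError("need at least one numerator spec")
    if not (math.isfinite(scale) and scale > 0):
        raise DataError(f"scale must be > 0, got {scale!r}")
    mu = sum(s.mu for s in numerators) - sum(s.mu for s in denominators) + math.log(scale)
    var = sum(s.sigma**2 for s in numerators) + sum(s.sigma**2 for s in denominators)
    if var == 0.0:
        return LognormalSpec.point_mass(math.exp(mu), unit_label)
    return LognormalSpec(mu=mu, sigma=math.sqrt(var), unit_label=unit_label)


def rsd(summary: SummaryMoments) -> float:
    """Relative standard deviation SD/mean (unitless dispersion measure)."""
    return summary.sd / summary.mean


def compare_fit_to_percentiles(spec: LognormalSpec, table: PercentileTable) -> dict:
    """Diagnostic: how well a fitted lognormal reproduces a percentile table.

    Returns per-entry relative errors of the fitted quantiles against the
    tabulated values plus the maximum absolute relative error.  Used to flag
    summary rows whose printed moments and percentiles are mutually
    inconsistent under a single lognormal (they exist in real exposure
    tables), without silently correcting either.
    """
    fitted = np.array([spec.quantile(p) for p in table.probabilities])
    rel = (fitted - table.values) / table.values
    return {
        "probabilities": table.probabilities.tolist(),
        "tabulated": table.values.tolist(),
        "fitted": fitted.tolist(),
        "relative_error": rel.tolist(),
        "max_abs_relative_error": float(np.max(np.abs(rel))),
    }
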