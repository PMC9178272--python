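"""Distribution characterization: KDE, Gaussian fit, bootstrap moments.

Across-fly distributions of a behavioral measure are summarized by

* a Gaussian-kernel density estimate with an optional bootstrap band,
* the maximum-likelihood normal fit (sample mean and SD),
* standardized moments to arbitrary order, with bootstrap uncertainty
  (order 1 = mean, order 2 = variance, order k ≥ 3 = E[((x−x̄)/s)^k];
  kurtosis is reported non-excess, so the Gaussian reference value is 3),
* stability of those moment estimates under random subsampling.

Bootstrap convention throughout the package: resampling is fly-wise,
B replicates of equal size with replacement, and the 95% confidence
interval is the point estimate ± twice the standard deviation of the
replicate values.  A replicate on which the statistic is undefined is
recorded as missing, excluded, and counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "DegenerateScaleError",
    "MomentReport",
    "BootstrapResult",
    "DensityEstimate",
    "StabilityCurve",
    "standardized_moment",
    "bootstrap_statistic",
    "moment_panel",
    "stability_curve",
    "kde",
    "gaussian_fit",
]

DEFAULT_B = 1_000  # bootstrap replicates
DEFAULT_MAX_ORDER = 20  # moments reported in the standard panel
SIGNIF_RATIO_THRESHOLD = 2.0  # |mean|/SD ≥ 2 ≈ p < 0.05 against zero


class DegenerateScaleError(ValueError):
    """Standardization is impossible: the sample has zero spread."""


@dataclass
class MomentReport:
    """Bootstrap characterization of one standardized moment."""

    order: int
    point_estimate: float
    boot_mean: float
    boot_sd: float
    ci_low: float
    ci_high: float
    signif_ratio: float
    n_failed: int = 0

    @property
    def significant(self) -> bool:
        """Distinguishable from zero at ~p = 0.05 (|mean|/SD ≥ 2)."""
        return self.signif_ratio >= SIGNIF_RATIO_THRESHOLD

    def to_dict(self) -> dict:
        return {
            "order": self.order,
            "point_estimate": self.point_estimate,
            "boot_mean": self.boot_mean,
            "boot_sd": self.boot_sd,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "signif_ratio": self.signif_ratio,
            "n_failed": self.n_failed,
        }


@dataclass
class BootstrapResult:
    point_estimate: float
    replicates: np.ndarray
    boot_mean: float
    boot_sd: float
    ci_low: float
    ci_high: float
    n_failed: int = 0


@dataclass
class DensityEstimate:
    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    ci_band: tuple[np.ndarray, np.ndarray] | None = None

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))

    def mode(self) -> float:
        return float(self.grid[np.argmax(self.density)])


@dataclass
class StabilityCurve:
    fractions: tuple[float, ...]
    sample_sizes: dict = field(default_factory=dict)
    panels: dict = field(default_factory=dict)  # fraction -> list[MomentReport]

    def orders_losing_significance(self) -> dict:
        """Orders significant at the largest fraction but not at each smaller one."""
        fracs = sorted(self.fractions, reverse=True)
        full = {r.order for r in self.panels[fracs[0]] if r.significant}
        return {
            f: sorted(full - {r.order for r in self.panels[f] if r.significant})
            for f in fracs[1:]
        }


def _clean(values) -> np.ndarray:
    x = np.asarray(values, dtype=float).ravel()
    x = x[np.isfinite(x)]
    return x


def standardized_moment(values, k: int) -> float:
    """k-th moment of the empirical distribution.

    Order 1 returns the mean and order 2 the variance; for k ≥ 3 the
    moment is standardized, (1/m)·Σ((x−x̄)/s)^k with s the sample SD,
    so order 3 is skewness and order 4 non-excess kurtosis.
    """
    if k < 1:
        raise ValueError("moment order must be ≥ 1")
    x = _clean(values)
    if x.size < 3:
        raise ValueError("need at least 3 finite values")
    if k == 1:
        return float(x.mean())
    s = x.std(ddof=1)
    if s == 0:
        raise DegenerateScaleError("sample has zero standard deviation")
    if k == 2:
        return float(s**2)
    return float(np.mean(((x - x.mean()) / s) ** k))


def _moment_vector(x: np.ndarray, max_order: int) -> np.ndarray:
    """Moments of orders 1..max_order in one pass (shared centering)."""
    m = x.mean()
    s = x.std(ddof=1)
    out = np.empty(max_order)
    out[0] = m
    if max_order == 1:
        return out
    if s == 0:
        out[1:] = np.nan
        return out
    out[1] = s**2
    z = (x - m) / s
    p = z * z
    for k in range(3, max_order + 1):
        p = p * z
        out[k - 1] = p.mean()
    return out


def bootstrap_statistic(
    values,
    statistic,
    B: int = DEFAULT_B,
    seed=None,
    rng: np.random.Generator | None = None,
) -> BootstrapResult:
    """Fly-wise bootstrap of an arbitrary statistic.

    Draws ``B`` equal-size resamples with replacement, applies
    ``statistic`` to each, and reports the ±2·SD confidence interval
    around the full-sample point estimate.  The replicate stream is
    reproducible from ``seed``.
    """
    if B < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("values must be non-empty")
    if rng is None:
        rng = np.random.default_rng(seed)
    point = float(statistic(x))
    reps = np.full(B, np.nan)
    n = x.size
    for b in range(B):
        idx = rng.integers(0, n, n)
        try:
            reps[b] = statistic(x[idx])
        except (ValueError, ZeroDivisionError, FloatingPointError):
            continue
    good = reps[np.isfinite(reps)]
    n_failed = B - good.size
    if n_failed:
        logger.warning("bootstrap: %d/%d replicate(s) undefined, excluded", n_failed, B)
    if good.size < 2:
        raise ValueError("statistic undefined on nearly all bootstrap replicates")
    sd = float(good.std(ddof=1))
    return BootstrapResult(
        point_estimate=point,
        replicates=reps,
        boot_mean=float(good.mean()),
        boot_sd=sd,
        ci_low=point - 2.0 * sd,
        ci_high=point + 2.0 * sd,
        n_failed=n_failed,
    )


def moment_panel(
    values,
    max_order: int = DEFAULT_MAX_ORDER,
    B: int = DEFAULT_B,
    seed=None,
    rng: np.random.Generator | None = None,
) -> list[MomentReport]:
    """Bootstrap panel of moments of orders 1..max_order.

    All orders are evaluated on one shared stream of resamples, so the
    panel is internally consistent (order 4 and order 6 of replicate b
    come from the same resample).  ``signif_ratio`` = |bootstrap mean| /
    bootstrap SD is the panel's significance measure against zero.
    """
    if max_order < 2:
        raise ValueError("max_order must be ≥ 2")
    x = _clean(values)
    if x.size < 3:
        raise ValueError("need at least 3 finite values")
    if x.std(ddof=1) == 0:
        raise DegenerateScaleError("sample has zero standard deviation")
    if rng is None:
        rng = np.random.default_rng(seed)
    point = _moment_vector(x, max_order)
    reps = np.full((B, max_order), np.nan)
    n = x.size
    for b in range(B):
        idx = rng.integers(0, n, n)
        reps[b] = _moment_vector(x[idx], max_order)
    reports = []
    for k in range(1, max_order + 1):
        col = reps[:, k - 1]
        good = col[np.isfinite(col)]
        bm = float(good.mean())
        bs = float(good.std(ddof=1))
        reports.append(
            MomentReport(
                order=k,
                point_estimate=float(point[k - 1]),
                boot_mean=bm,
                boot_sd=bs,
                ci_low=float(point[k - 1]) - 2.0 * bs,
                ci_high=float(point[k - 1]) + 2.0 * bs,
                signif_ratio=abs(bm) / bs if bs > 0 else np.inf,
                n_failed=int(B - good.size),
            )
        )
    return reports


def stability_curve(
    values,
    max_order: int = DEFAULT_MAX_ORDER,
    fractions=(1.0, 0.1, 0.01),
    B: int = DEFAULT_B,
    seed=None,
    repeats: int = 1,
) -> StabilityCurve:
    """Moment panels on nested random subsamples of the data.

    For each fraction a single random subset is drawn without
    replacement (seeded) and :func:`moment_panel` applied; with
    ``repeats`` > 1 the panels of extra draws are stored under keys
    ``(fraction, repeat)`` for dispersion studies.
    """
    x = _clean(values)
    fractions = tuple(sorted(set(float(f) for f in fractions), reverse=True))
    if any(f > 1 or f <= 0 for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    if round(min(fractions) * x.size) < 10:
        raise ValueError("smallest fraction leaves fewer than 10 values")
    rng = np.random.default_rng(seed)
    curve = StabilityCurve(fractions=fractions)
    for f in fractions:
        m = int(round(f * x.size))
        for r in range(repeats):
            sub = x if f == 1.0 else x[rng.choice(x.size, size=m, replace=False)]
            panel = moment_panel(sub, max_order=max_order, B=B, rng=rng)
            curve.panels[f if r == 0 else (f, r)] = panel
        curve.sample_sizes[f] = m
    return curve


def kde(
    values,
    bandwidth: float | None = None,
    grid=512,
    B: int = 0,
    seed=None,
) -> DensityEstimate:
    """Gaussian-kernel density estimate on a regular grid.

    ``bandwidth`` is the absolute kernel SD; ``None`` selects
    Silverman's rule.  No boundary correction is applied at the ends of
    the support.  With ``B`` > 0 a per-grid-point ±2·SD bootstrap band
    is attached.
    """
    x = _clean(values)
    if x.size < 10:
        raise ValueError("need at least 10 values for a density estimate")
    if bandwidth is not None and bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    sd = x.std(ddof=1)
    if sd == 0:
        raise DegenerateScaleError("sample has zero spread")
    bw_method = None if bandwidth is None else bandwidth / sd
    k = stats.gaussian_kde(x, bw_method=bw_method)
    h = float(np.sqrt(k.covariance[0, 0]))
    if np.isscalar(grid):
        grid_arr = np.linspace(x.min() - 3 * h, x.max() + 3 * h, int(grid))
    else:
        grid_arr = np.asarray(grid, dtype=float)
    density = k(grid_arr)
    band = None
    if B > 0:
        rng = np.random.default_rng(seed)
        reps = np.empty((B, grid_arr.size))
        for b in range(B):
            xb = x[rng.integers(0, x.size, x.size)]
            reps[b] = stats.gaussian_kde(xb, bw_method=h / xb.std(ddof=1))(grid_arr)
        rep_sd = reps.std(axis=0, ddof=1)
        band = (np.clip(density - 2 * rep_sd, 0, None), density + 2 * rep_sd)
    return DensityEstimate(grid=grid_arr, density=density, bandwidth=h, ci_band=band)


def gaussian_fit(values) -> tuple[float, float]:
    """Maximum-likelihood normal parameters (mean, SD with ddof=0)."""
    x = _clean(values)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    mu, sd = float(x.mean()), float(x.std(ddof=0))
    if sd == 0:
        logger.warning("gaussian_fit: constant input, SD = 0")
    return mu, sd
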