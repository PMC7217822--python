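"""Progression statistics for visual-field series.

Implements mean-total-deviation (mTD) trend analysis by ordinary or
weighted least squares, extrapolation of the fitted trend to predict a
future exam, pointwise linear regression (PLR) at each of the 52 test
locations, and the binomial PLR whole-field statistic.  Each analysis has a
reconstruction-weighted variant: an exam (or a single point) whose measured
value sits close to its VAE reconstruction is presumed reliable and receives
weight ``1 / |measured - reconstructed|``; exams the autoencoder cannot
explain are down-weighted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .vf_core import N_POINTS, VFSeries

#: PLR p-value cutoffs of the binomial whole-field test
BINOMIAL_CUTOFFS = (0.025, 0.05, 0.075, 0.1)

#: binomial-PLR significance rule: median binomial p below this
BINOMIAL_ALPHA = 0.025

#: mTD-trend significance rule: negative slope with two-sided p below this
TREND_ALPHA = 0.05

_WEIGHT_MODES = ("unweighted", "vae_mtd", "vae_pointwise")


@dataclass
class WeightScheme:
    """How regression weights are derived from VAE reconstructions.

    ``epsilon`` floors the absolute measurement-reconstruction difference
    (dB) so that a perfect reconstruction yields a finite weight.
    """

    mode: str = "unweighted"
    epsilon: float = 0.01

    def __post_init__(self) -> None:
        if self.mode not in _WEIGHT_MODES:
            raise ValueError(f"mode must be one of {_WEIGHT_MODES}, got {self.mode!r}")
        if not self.epsilon > 0:
            raise ValueError("epsilon must be > 0")


@dataclass
class RegressionFit:
    """A straight-line fit of a dB quantity on time."""

    slope: float  # dB/year
    intercept: float  # dB at t = 0
    slope_p: float  # two-sided p-value of the slope (nan when n < 3)
    n: int
    weights: np.ndarray

    def predict(self, t) -> np.ndarray | float:
        return self.intercept + self.slope * np.asarray(t, dtype=float)


@dataclass
class BinomialPLRResult:
    """Whole-field progression call from 52 pointwise regression p-values."""

    per_point_p: np.ndarray
    counts_below: dict[float, int]
    binom_p: dict[float, float]
    median_p: float
    significant: bool


def _wls_columns(t: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Weighted least squares of each column of ``y`` on ``t``.

    ``y`` and ``w`` are ``(n, p)``; returns per-column slope, intercept,
    two-sided p, and one-sided (deterioration, slope < 0) p.
    """
    n = len(t)
    sw = w.sum(axis=0)
    if np.any(sw <= 0):
        raise ValueError("weights must include at least one positive value")
    tbar = (w * t[:, None]).sum(axis=0) / sw
    ybar = (w * y).sum(axis=0) / sw
    tc = t[:, None] - tbar
    sxx = (w * tc**2).sum(axis=0)
    if np.any(sxx <= 1e-12):
        raise ValueError("degenerate design: need positive weight at >= 2 distinct times")
    sxy = (w * tc * (y - ybar)).sum(axis=0)
    slope = sxy / sxx
    intercept = ybar - slope * tbar
    if n < 3:
        nan = np.full_like(slope, np.nan)
        return slope, intercept, nan, nan
    resid = y - intercept - slope * t[:, None]
    s2 = (w * resid**2).sum(axis=0) / (n - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(s2 / sxx)
        tstat = slope / se
    df = n - 2
    # exact fits: zero residual variance makes the slope estimate certain
    exact = se == 0
    signed_inf = np.where(slope > 0, np.inf, np.where(slope < 0, -np.inf, 0.0))
    tstat = np.where(exact, signed_inf, tstat)
    with np.errstate(invalid="ignore"):
        p_two = 2.0 * stats.t.sf(np.abs(tstat), df)
        p_one = stats.t.cdf(tstat, df)
    p_two = np.where(exact & (slope == 0), 1.0, p_two)
    p_one = np.where(exact & (slope == 0), 0.5, p_one)
    return slope, intercept, p_two, p_one


def weighted_fit(t, y, w) -> RegressionFit:
    """Minimize the weighted residual sum of squares Σ wᵢ(yᵢ − a − b·tᵢ)².

    Equal weights reproduce :func:`ols_fit` exactly; the slope p-value is a
    two-sided t-test on ``n - 2`` degrees of freedom.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    if not (t.shape == y.shape == w.shape and t.ndim == 1):
        raise ValueError("t, y and w must be 1-D arrays of equal length")
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    if len(np.unique(t[w > 0])) < 2:
        raise ValueError("degenerate design: need positive weight at >= 2 distinct times")
    slope, intercept, p_two, _ = _wls_columns(t, y[:, None], w[:, None])
    return RegressionFit(
        slope=float(slope[0]),
        intercept=float(intercept[0]),
        slope_p=float(p_two[0]),
        n=len(t),
        weights=w,
    )


def ols_fit(t, y) -> RegressionFit:
    """Ordinary least-squares straight-line regression of ``y`` on ``t``."""
    t = np.asarray(t, dtype=float)
    return weighted_fit(t, y, np.ones_like(t))


def vae_weights(
    series: VFSeries, recon_series: VFSeries | None, scheme: WeightScheme
) -> np.ndarray:
    """Regression weights from reconstruction agreement.

    Returns a per-exam vector ``(n,)`` for modes ``unweighted``/``vae_mtd``
    and a per-exam-per-point matrix ``(n, 52)`` for ``vae_pointwise``:

    - ``vae_mtd``:        wᵢ   = 1 / max(ε, |mTDᵢ − mTD_VAEᵢ|)
    - ``vae_pointwise``:  wᵢⱼ = 1 / max(ε, |TDᵢⱼ − TD_VAEᵢⱼ|)
    """
    n = len(series)
    if scheme.mode == "unweighted":
        return np.ones(n)
    if recon_series is None:
        raise ValueError(f"mode {scheme.mode!r} requires a reconstructed series")
    if len(recon_series) != n:
        raise ValueError(
            f"series ({n} exams) and reconstruction ({len(recon_series)}) are misaligned"
        )
    if scheme.mode == "vae_mtd":
        diff = np.abs(series.mtd - recon_series.mtd)
        return 1.0 / np.maximum(scheme.epsilon, diff)
    diff = np.abs(series.td_matrix - recon_series.td_matrix)
    return 1.0 / np.maximum(scheme.epsilon, diff)


def _exam_weights(series, recon, scheme) -> np.ndarray:
    w = vae_weights(series, recon, scheme)
    if w.ndim == 2:  # pointwise weights collapse to per-exam for mTD fits
        w = w.mean(axis=1)
    return w


def mtd_trend(
    series: VFSeries,
    scheme: WeightScheme | None = None,
    recon: VFSeries | None = None,
) -> RegressionFit:
    """(Weighted) linear regression of per-exam mTD on time."""
    scheme = scheme or WeightScheme()
    return weighted_fit(series.times, series.mtd, _exam_weights(series, recon, scheme))


def trend_is_significant(fit: RegressionFit, alpha: float = TREND_ALPHA) -> bool:
    """Progression call for an mTD trend: worsening slope, two-sided p < α."""
    return bool(fit.slope < 0 and np.isfinite(fit.slope_p) and fit.slope_p < alpha)


def predict_future_mtd(
    series: VFSeries,
    scheme: WeightScheme | None = None,
    recon: VFSeries | None = None,
    t_target: float = 0.0,
) -> float:
    """Extrapolate the (weighted) mTD trend of ``series`` to ``t_target``."""
    fit = mtd_trend(series, scheme, recon)
    return float(fit.predict(t_target))


def pointwise_plr(
    series: VFSeries,
    scheme: WeightScheme | None = None,
    recon: VFSeries | None = None,
    alternative: str = "less",
) -> tuple[list[RegressionFit], np.ndarray]:
    """Per-point (weighted) regression of TD on time at all 52 locations.

    Returns the 52 fits and the per-point deterioration p-values: one-sided
    ``P(slope < observed | no change)`` by default (uniform under the null,
    as the binomial whole-field test requires), two-sided with
    ``alternative='two-sided'``.
    """
    if alternative not in ("less", "two-sided"):
        raise ValueError("alternative must be 'less' or 'two-sided'")
    scheme = scheme or WeightScheme()
    if len(series) < 3:
        raise ValueError("pointwise PLR needs at least 3 exams")
    t = series.times
    y = series.td_matrix
    w = vae_weights(series, recon, scheme)
    if w.ndim == 1:
        w = np.broadcast_to(w[:, None], y.shape).copy()
    slope, intercept, p_two, p_one = _wls_columns(t, y, w)
    fits = [
        RegressionFit(float(slope[j]), float(intercept[j]), float(p_two[j]), len(t), w[:, j])
        for j in range(y.shape[1])
    ]
    return fits, (p_one if alternative == "less" else p_two)


def binomial_plr(per_point_p) -> BinomialPLRResult:
    """Whole-field progression test on 52 pointwise p-values.

    Under no change the pointwise p-values are uniform, so the number below
    a cutoff ``c`` is Binomial(52, c).  The exact upper tail
    ``P(X >= k_c)`` is evaluated at cutoffs 0.025/0.05/0.075/0.1; the
    representative p-value is the median of the four tail probabilities
    (mean of the two middle order statistics) and the field is called
    significant when it falls below 0.025.
    """
    p = np.asarray(per_point_p, dtype=float)
    if p.shape != (N_POINTS,):
        raise ValueError(f"expected {N_POINTS} p-values, got shape {p.shape}")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must be finite and in [0, 1]")
    counts = {c: int(np.sum(p < c)) for c in BINOMIAL_CUTOFFS}
    binom_p = {
        c: float(stats.binom.sf(k - 1, N_POINTS, c)) for c, k in counts.items()
    }
    ordered = np.sort(list(binom_p.values()))
    median_p = float(0.5 * (ordered[1] + ordered[2]))
    return BinomialPLRResult(
        per_point_p=p,
        counts_below=counts,
        binom_p=binom_p,
        median_p=median_p,
        significant=bool(median_p < BINOMIAL_ALPHA),
    )


def binomial_plr_series(
    series: VFSeries,
    scheme: WeightScheme | None = None,
    recon: VFSeries | None = None,
) -> BinomialPLRResult:
    """Pointwise PLR followed by the binomial whole-field test."""
    _, p = pointwise_plr(series, scheme, recon)
    return binomial_plr(p)
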