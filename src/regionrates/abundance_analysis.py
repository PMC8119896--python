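"""Abundance stratification, region-rate coupling, and trend fits.

Proteins are binned into abundance classes on PaxDb-style ppm values
(default edges 0, 3, 18, 59, 352, 21866 ppm; left-open, right-closed
intervals with the first closed at 0).  Within each class the coupling
between two region means across proteins is the Spearman rank correlation
with a two-sided p-value from the t approximation.  The stability of a
conservation ratio across abundance is tested by a global Spearman of ratio
against ppm plus per-class median/MAD/IQR summaries, and the evolutionary
rate versus log10 abundance trend is fitted with a four-parameter logistic
(4PL) curve by multi-start least squares.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io_formats import ConfigurationError
from .region_stats import RatioSummary, summarize_ratios

logger = logging.getLogger("regionrates.abundance")

__all__ = [
    "DEFAULT_BIN_EDGES",
    "AbundanceBins",
    "CouplingResult",
    "SigmoidFit",
    "bin_by_abundance",
    "spearman",
    "coupling_by_class",
    "ratio_abundance_trend",
    "fit_sigmoid",
    "log10_with_offset",
]

DEFAULT_BIN_EDGES = (0.0, 3.0, 18.0, 59.0, 352.0, 21866.0)


@dataclass
class AbundanceBins:
    """Strictly increasing ppm edges defining left-open, right-closed classes.

    The first interval is closed at 0 (ppm = 0 falls in class 1); values
    above the top edge are assigned to the top class with a logged warning.
    """

    edges: tuple[float, ...] = DEFAULT_BIN_EDGES

    def __post_init__(self) -> None:
        edges = tuple(float(e) for e in self.edges)
        if len(edges) < 2 or any(b <= a for a, b in zip(edges, edges[1:])):
            raise ConfigurationError("bin edges must be strictly increasing, >= 2 values")
        self.edges = edges

    @property
    def labels(self) -> list[str]:
        def fmt(x: float) -> str:
            return f"{x:g}"

        return [
            f"{fmt(a)}-{fmt(b)}" for a, b in zip(self.edges, self.edges[1:])
        ]

    @property
    def n_classes(self) -> int:
        return len(self.edges) - 1


@dataclass
class CouplingResult:
    class_label: str
    numerator_region: str
    denominator_region: str
    n_proteins: int
    spearman_rho: float
    p_value: float


@dataclass
class SigmoidFit:
    """4PL fit er = lower + (upper - lower) / (1 + exp(slope * (x - midpoint)))."""

    lower: float
    upper: float
    midpoint: float
    slope: float
    rss: float
    converged: bool
    degenerate: bool = False


def bin_by_abundance(
    ppm: pd.Series | np.ndarray,
    bins: AbundanceBins | None = None,
) -> pd.Series:
    """Assign each protein's ppm to an abundance class label.

    Missing ppm yields a missing label (the caller's exclusion report
    counts them).  Values above the top edge go to the top class with a
    warning.
    """
    bins = bins or AbundanceBins()
    vals = pd.Series(np.asarray(ppm, dtype=float))
    over = vals > bins.edges[-1]
    if over.any():
        logger.warning(
            "%d ppm value(s) above the top bin edge %g assigned to the top class",
            int(over.sum()),
            bins.edges[-1],
        )
        vals = vals.clip(upper=bins.edges[-1])
    cut = pd.cut(
        vals,
        bins=list(bins.edges),
        right=True,
        include_lowest=True,
        labels=bins.labels,
    )
    out = pd.Series(cut.astype(object))
    if isinstance(ppm, pd.Series):
        out.index = ppm.index
    return out


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided t-approximation p-value.

    Incomplete pairs are dropped; fewer than 3 complete pairs, or zero rank
    variance in either variable, yields (nan, nan).  Ranks are averaged
    over ties.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        return math.nan, math.nan
    if np.all(x == x[0]) or np.all(y == y[0]):
        logger.warning("spearman: zero variance in one variable; rho undefined")
        return math.nan, math.nan
    res = stats.spearmanr(x, y, alternative="two-sided")
    rho = float(res.statistic)
    if not np.isfinite(rho):
        return math.nan, math.nan
    return rho, float(res.pvalue)


def coupling_by_class(
    region_means: pd.DataFrame,
    classes: pd.Series,
    pair: tuple[str, str],
    bins: AbundanceBins | None = None,
) -> list[CouplingResult]:
    """Per-class Spearman coupling of two region means across proteins.

    ``region_means`` is indexed by protein_id with one column per region
    (mean rates, NaN when undefined); ``classes`` maps protein_id to class
    label.  Proteins contribute only when both means are defined.  Classes
    with fewer than 3 such proteins get NaN statistics.
    """
    bins = bins or AbundanceBins()
    num, den = pair
    out = []
    for label in bins.labels:
        pids = classes.index[classes == label]
        sub = region_means.reindex(pids)[[num, den]].dropna()
        rho, p = spearman(sub[num], sub[den]) if len(sub) >= 3 else (math.nan, math.nan)
        out.append(
            CouplingResult(
                class_label=label,
                numerator_region=num,
                denominator_region=den,
                n_proteins=len(sub),
                spearman_rho=rho,
                p_value=p,
            )
        )
    return out


def ratio_abundance_trend(
    ratios: pd.Series,
    ppm: pd.Series,
    bins: AbundanceBins | None = None,
) -> tuple[float, float, pd.DataFrame]:
    """Global Spearman of ratio vs ppm plus per-class robust summaries.

    ``ratios`` and ``ppm`` are aligned by protein_id index.  Returns
    (rho, p, per_class) where per_class has one row per abundance class:
    n, median, mad, q1, q3, whisker_low, whisker_high (whiskers at
    1.58 x IQR beyond the quartiles, clipped to the data range).
    """
    bins = bins or AbundanceBins()
    joined = pd.DataFrame({"ratio": ratios, "ppm": ppm}).dropna()
    rho, p = spearman(joined["ratio"], joined["ppm"])
    classes = bin_by_abundance(joined["ppm"], bins)
    rows = []
    for label in bins.labels:
        vals = joined.loc[classes == label, "ratio"].to_numpy()
        summary = summarize_ratios(vals)
        if summary.n_proteins:
            q1, q3 = np.percentile(vals, [25, 75])
            iqr = q3 - q1
            wlo = float(max(vals.min(), q1 - 1.58 * iqr))
            whi = float(min(vals.max(), q3 + 1.58 * iqr))
        else:
            q1 = q3 = wlo = whi = math.nan
        rows.append(
            (label, summary.n_proteins, summary.median_ratio, summary.mad,
             float(q1), float(q3), wlo, whi)
        )
    per_class = pd.DataFrame(
        rows,
        columns=["class", "n_proteins", "median_ratio", "mad", "q1", "q3",
                 "whisker_low", "whisker_high"],
    )
    return rho, p, per_class


def log10_with_offset(ppm: np.ndarray | pd.Series) -> np.ndarray:
    """log10(ppm + eps) with eps = smallest positive observed ppm / 10.

    Admits ppm = 0 into log-abundance analyses.
    """
    vals = np.asarray(ppm, dtype=float)
    positive = vals[np.isfinite(vals) & (vals > 0)]
    eps = float(positive.min()) / 10.0 if len(positive) else 1e-6
    return np.log10(vals + eps)


def _sigmoid(x: np.ndarray, lower: float, upper: float, mid: float, slope: float) -> np.ndarray:
    return lower + (upper - lower) / (1.0 + np.exp(slope * (x - mid)))


def fit_sigmoid(log10_ppm, er, degenerate_tol: float = 1e-6) -> SigmoidFit:
    """Least-squares 4PL fit of rate against log10 abundance.

    Requires >= 8 points spanning >= 1 decade.  Multi-start initialization:
    midpoints at the 25/50/75th percentiles of x, slopes +-1, asymptotes
    from the 5th/95th percentiles of y; best residual sum of squares wins,
    ties broken by smaller |slope|.  Parameters are canonicalized so
    lower <= upper (flipping the slope sign, which leaves the curve
    unchanged).  Non-convergence from every start returns the best-found
    parameters with ``converged=False``.
    """
    x = np.asarray(log10_ppm, dtype=float)
    y = np.asarray(er, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 8:
        raise ConfigurationError("sigmoid fit requires >= 8 points")
    if x.max() - x.min() < 1.0:
        raise ConfigurationError("sigmoid fit requires >= 1 decade of abundance")
    y_lo, y_hi = np.percentile(y, [5, 95])
    if y_hi - y_lo < degenerate_tol:
        return SigmoidFit(
            lower=float(np.mean(y)), upper=float(np.mean(y)),
            midpoint=float(np.median(x)), slope=0.0,
            rss=float(np.sum((y - np.mean(y)) ** 2)),
            converged=True, degenerate=True,
        )

    def residuals(theta: np.ndarray) -> np.ndarray:
        return _sigmoid(x, *theta) - y

    best = None
    any_converged = False
    for mid in np.percentile(x, [25, 50, 75]):
        for slope in (1.0, -1.0):
            theta0 = np.array([y_lo, y_hi, mid, slope])
            try:
                res = optimize.least_squares(residuals, theta0, method="lm", max_nfev=5000)
            except Exception:
                continue
            rss = float(np.sum(res.fun**2))
            cand = (rss, abs(float(res.x[3])), res.x, bool(res.success))
            if best is None or (cand[0], cand[1]) < (best[0], best[1]):
                best = cand
            any_converged = any_converged or bool(res.success)
    if best is None:
        raise ConfigurationError("sigmoid fit failed from every start")
    rss, _, theta, _ = best
    lower, upper, mid, slope = (float(v) for v in theta)
    if lower > upper:
        lower, upper, slope = upper, lower, -slope
    degenerate = (upper - lower) < degenerate_tol
    return SigmoidFit(
        lower=lower, upper=upper, midpoint=mid, slope=slope,
        rss=rss, converged=any_converged, degenerate=degenerate,
    )
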