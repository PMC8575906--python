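"""Spawning-stage classification from wholemount diameters.

Two related tools live here:

* the oocyte ratio OR = ΣPVO / Σ(VO + FOM) computed from cleaned wholemount
  diameters with a fixed previtellogenic/developing split (default 230 µm),
  binned into oocyte-ratio categories ORC0–ORC4 (prespawning → spent);
* a two-component Gamma + Gaussian mixture fitted by EM to a female's
  diameter distribution, whose posterior-0.5 crossing estimates the
  PVO/developing diameter threshold when no clear hiatus exists.

ORC0 is metadata-driven: the rule table assigns no OR range to prespawning
fish, so the ``prespawning_flag`` on the biometry record is authoritative.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .core_types import FemaleRecord

__all__ = [
    "DEFAULT_PVO_MAX",
    "LEGACY_PVO_MAX",
    "MIN_DIAMETER",
    "MAX_DIAMETER",
    "CleaningReport",
    "clean_wholemount",
    "compute_or",
    "classify_orc",
    "derive_prespawning_flag",
    "orc_table",
    "MixtureFit",
    "fit_gamma_gaussian_mixture",
    "threshold_summary",
    "smoothed_osfd",
]

#: previtellogenic/developing diameter split established histologically (µm)
DEFAULT_PVO_MAX = 230.0
#: historical split used in legacy fecundity protocols (µm)
LEGACY_PVO_MAX = 185.0
#: smallest analysable diameter — tinier oocytes wash out during staining (µm)
MIN_DIAMETER = 100.0
#: largest usable diameter — the follicle layer detaches above ~1150 µm (µm)
MAX_DIAMETER = 1100.0


@dataclass
class CleaningReport:
    female_id: str
    n_raw: int
    n_kept: int
    n_below: int
    n_above: int
    flagged_sub_minimum: bool  # raw data contained sub-minimum detections


def clean_wholemount(
    raw_diameters: Sequence[float],
    min_d: float = MIN_DIAMETER,
    max_d: float = MAX_DIAMETER,
    female_id: str = "",
) -> tuple[np.ndarray, CleaningReport]:
    """Restrict raw diameters to the analysable window [min_d, max_d].

    Females whose raw measurements contain sub-minimum detections are flagged
    (the source protocol excluded such females outright); the caller decides
    whether the flag is disqualifying. Raises when nothing survives.
    """
    d = np.asarray(raw_diameters, dtype=float)
    below = d < min_d
    above = d > max_d
    kept = d[~below & ~above]
    if kept.size == 0:
        raise ValueError(f"female {female_id or '?'}: no analysable oocytes after cleaning")
    return kept, CleaningReport(
        female_id=female_id,
        n_raw=int(d.size),
        n_kept=int(kept.size),
        n_below=int(below.sum()),
        n_above=int(above.sum()),
        flagged_sub_minimum=bool(below.any()),
    )


def compute_or(
    diameters: Sequence[float], pvo_max: float = DEFAULT_PVO_MAX
) -> tuple[int, int, float]:
    """Count PVO-sized vs developing-sized oocytes and form the oocyte ratio.

    Diameter alone decides the split in wholemount data (cortical alveoli
    oocytes count on the developing side). Returns ``(n_pvo, n_dev, OR)``;
    OR is ``+inf`` when no developing oocytes are present.
    """
    d = np.asarray(diameters, dtype=float)
    if d.size == 0:
        raise ValueError("empty diameter vector")
    n_pvo = int(np.sum(d <= pvo_max))
    n_dev = int(d.size - n_pvo)
    ratio = n_pvo / n_dev if n_dev > 0 else float("inf")
    return n_pvo, n_dev, ratio


def classify_orc(oocyte_ratio: float, prespawning_flag: bool = False) -> int:
    """Bin an oocyte ratio into the rule-table categories 0–4.

    ORC0 (prespawning) comes only from the flag; the OR bands are closed on
    their upper end: OR ≤ 1 → 1 (early), 1 < OR ≤ 3 → 2 (mid),
    3 < OR ≤ 15 → 3 (late), OR > 15 (incl. +inf) → 4 (very late / spent).
    """
    if prespawning_flag:
        return 0
    if math.isnan(oocyte_ratio) or oocyte_ratio < 0:
        raise ValueError(f"invalid oocyte ratio {oocyte_ratio}")
    if oocyte_ratio <= 1.0:
        return 1
    if oocyte_ratio <= 3.0:
        return 2
    if oocyte_ratio <= 15.0:
        return 3
    return 4


def derive_prespawning_flag(
    record: FemaleRecord,
    spawning_months: Sequence[int] = (3, 4, 5, 6, 7),
    max_developing_fraction: float = 0.05,
    developing_fraction: Optional[float] = None,
) -> bool:
    """Heuristic prespawning flag: captured before the spawning season and at
    most a trace of developing oocytes. Provided as a convenience only — the
    flag stored on the record is authoritative for classification."""
    before_season = record.month < min(spawning_months)
    if developing_fraction is None:
        return before_season
    return before_season and developing_fraction <= max_developing_fraction


def orc_table(
    wholemount: pd.DataFrame,
    females: pd.DataFrame,
    pvo_max: float = DEFAULT_PVO_MAX,
    min_d: float = MIN_DIAMETER,
    max_d: float = MAX_DIAMETER,
    drop_flagged: bool = False,
) -> tuple[pd.DataFrame, list[CleaningReport]]:
    """Per-female ORC classification table from the two input tables.

    Returns ``(orc_df, cleaning_reports)`` where ``orc_df`` has columns
    female_id, n_pvo, n_dev, OR, ORC. With ``drop_flagged`` females whose raw
    data contained sub-minimum detections are excluded (the strict protocol).
    """
    flags = females.set_index("female_id")["prespawning_flag"].to_dict()
    rows = []
    reports = []
    for fid, grp in wholemount.groupby("female_id", sort=True):
        fid = str(fid)
        if fid not in flags:
            raise KeyError(f"wholemount female {fid} missing from biometry table")
        kept, report = clean_wholemount(
            grp["diameter_um"].to_numpy(), min_d=min_d, max_d=max_d, female_id=fid
        )
        reports.append(report)
        if drop_flagged and report.flagged_sub_minimum:
            continue
        n_pvo, n_dev, ratio = compute_or(kept, pvo_max=pvo_max)
        rows.append((fid, n_pvo, n_dev, ratio, classify_orc(ratio, bool(flags[fid]))))
    return (
        pd.DataFrame(rows, columns=["female_id", "n_pvo", "n_dev", "OR", "ORC"]),
        reports,
    )


# ---------------------------------------------------------------------------
# Gamma/Gaussian mixture


@dataclass
class MixtureFit:
    """Result of a two-component Gamma (lower) + Gaussian (upper) EM fit."""

    gamma_shape: float
    gamma_scale: float
    normal_mean: float
    normal_sd: float
    weight: float  # mixing proportion of the gamma component
    threshold: float  # µm, posterior-0.5 crossing between the component modes
    log_likelihood: float
    n_iter: int
    converged: bool
    loglik_trace: list[float] = field(default_factory=list, repr=False)

    @property
    def gamma_mode(self) -> float:
        a, s = self.gamma_shape, self.gamma_scale
        return (a - 1.0) * s if a > 1.0 else 0.0


def _initial_split(d: np.ndarray, window: tuple[float, float] = (150.0, 400.0)) -> float:
    """Empirical-density minimum between the two presumed modes."""
    lo = max(window[0], float(np.min(d)))
    hi = min(window[1], float(np.max(d)))
    if not hi > lo:
        return float(np.median(d))
    kde = stats.gaussian_kde(d)
    grid = np.linspace(lo, hi, 256)
    return float(grid[np.argmin(kde(grid))])


def _gamma_mle_shape(weighted_mean: float, weighted_meanlog: float) -> float:
    """Solve log(a) − ψ(a) = log(m) − <log d> for the gamma shape a."""
    c = math.log(weighted_mean) - weighted_meanlog
    if c <= 1e-12:  # degenerate: essentially zero dispersion
        return 1e6
    f = lambda a: math.log(a) - special.digamma(a) - c
    return float(optimize.brentq(f, 1e-3, 1e7, xtol=1e-10, rtol=1e-12))


def fit_gamma_gaussian_mixture(
    diameters: Sequence[float],
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: Optional[int] = None,
    upper_limit: Optional[float] = None,
) -> MixtureFit:
    """EM fit of w·Gamma(d) + (1−w)·Normal(d) to a diameter sample.

    Initialisation splits the data at the empirical density minimum between
    150 and 400 µm with method-of-moments parameters per side; the fit is
    deterministic given the data (``seed`` is accepted for interface
    stability but no stochastic restarts are currently performed).

    ``upper_limit`` drops diameters above the given value before fitting.
    The threshold lives between the previtellogenic bulk and the first
    developing mode; in ovaries holding several advanced cohorts the far
    vitellogenic/final-maturation tail destabilises the single-Gaussian
    upper component, so restricting the fit window (e.g. to ≤ 500 µm) is
    recommended when staging actively spawning females.

    The threshold is the smallest diameter between the gamma mode and the
    normal mean where the posterior probability of the Gaussian component
    reaches 0.5 — equivalently the weighted-density crossing.

    Raises on fewer than 50 points, on a one-sided initial split (< 10 points
    on either side — no evidence of bimodality), or on a degenerate fit
    (mixing weight collapsing to 0 or 1). Non-convergence within ``max_iter``
    returns ``converged=False`` with a warning rather than raising.
    """
    d = np.asarray(diameters, dtype=float)
    if upper_limit is not None:
        d = d[d <= upper_limit]
    if d.size < 50:
        raise ValueError(f"need at least 50 diameters for a mixture fit, got {d.size}")
    if np.any(d <= 0):
        raise ValueError("diameters must be positive")

    split = _initial_split(d)
    low, high = d[d <= split], d[d > split]
    if low.size < 10 or high.size < 10:
        raise ValueError(
            "bimodality precondition failed: fewer than 10 points on one side "
            f"of the initial split at {split:.0f} um"
        )

    w = low.size / d.size
    m, s = float(np.mean(low)), float(np.std(low)) or 1.0
    shape, scale = (m / s) ** 2, s**2 / m
    mu, sd = float(np.mean(high)), max(float(np.std(high)), 1e-3)

    logd = np.log(d)
    ll_prev = -np.inf
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step in log space for numerical safety
        log_g = stats.gamma.logpdf(d, a=shape, scale=scale) + math.log(w)
        log_n = stats.norm.logpdf(d, loc=mu, scale=sd) + math.log(1.0 - w)
        log_mix = np.logaddexp(log_g, log_n)
        ll = float(np.sum(log_mix))
        trace.append(ll)
        if ll + 1e-9 < ll_prev:  # EM guarantees monotone ascent
            raise AssertionError(f"log-likelihood decreased at iteration {it}")
        if abs(ll - ll_prev) < tol:
            converged = True
            break
        ll_prev = ll

        r = np.exp(log_g - log_mix)  # responsibility of the gamma component
        w = float(np.mean(r))
        if w < 1e-3 or w > 1.0 - 1e-3:
            raise ValueError("unimodal data: mixture weight collapsed")
        rsum = r.sum()
        wm = float(np.dot(r, d) / rsum)
        wml = float(np.dot(r, logd) / rsum)
        shape = _gamma_mle_shape(wm, wml)
        scale = wm / shape
        nsum = (1.0 - r).sum()
        mu = float(np.dot(1.0 - r, d) / nsum)
        sd = max(math.sqrt(float(np.dot(1.0 - r, (d - mu) ** 2) / nsum)), 1e-3)

    if not converged:
        warnings.warn(
            f"mixture EM did not converge within {max_iter} iterations", RuntimeWarning
        )

    fit = MixtureFit(
        gamma_shape=shape,
        gamma_scale=scale,
        normal_mean=mu,
        normal_sd=sd,
        weight=w,
        threshold=float("nan"),
        log_likelihood=trace[-1],
        n_iter=it,
        converged=converged,
        loglik_trace=trace,
    )
    fit.threshold = _posterior_threshold(fit)
    return fit


def _posterior_threshold(fit: MixtureFit) -> float:
    """Smallest d between the component modes with P(Normal | d) ≥ 0.5."""
    lo = max(fit.gamma_mode, 1e-6)
    hi = fit.normal_mean
    if not hi > lo:
        raise ValueError("normal mean does not exceed the gamma mode; no threshold")

    def excess(x: np.ndarray | float):
        log_g = stats.gamma.logpdf(x, a=fit.gamma_shape, scale=fit.gamma_scale) + math.log(
            fit.weight
        )
        log_n = stats.norm.logpdf(x, loc=fit.normal_mean, scale=fit.normal_sd) + math.log(
            1.0 - fit.weight
        )
        # posterior(normal) - 0.5 has the sign of log_n - log_g
        return log_n - log_g

    grid = np.linspace(lo, hi, 512)
    vals = np.asarray(excess(grid))
    if vals[0] >= 0:
        return float(lo)
    idx = np.flatnonzero(vals >= 0)
    if idx.size == 0:
        raise ValueError("no posterior-0.5 crossing between the component modes")
    i = idx[0]
    return float(optimize.brentq(excess, grid[i - 1], grid[i], xtol=1e-6))


def threshold_summary(fits: Sequence[MixtureFit]) -> tuple[float, tuple[float, float]]:
    """Across-female mean threshold with a t-distribution 95% CI.

    Only converged fits are used; fewer than two raise.
    """
    th = np.array([f.threshold for f in fits if f.converged], dtype=float)
    if th.size < 2:
        raise ValueError("need at least two converged fits for a threshold summary")
    mean = float(np.mean(th))
    sem = float(np.std(th, ddof=1) / math.sqrt(th.size))
    half = float(stats.t.ppf(0.975, th.size - 1)) * sem
    return mean, (mean - half, mean + half)


def smoothed_osfd(
    diameters: Sequence[float],
    bandwidth: Optional[float] = None,
    grid: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-kernel smoothed oocyte size frequency distribution.

    ``bandwidth`` is in µm (defaults to Silverman's rule); the density is
    renormalised to integrate to 1 over the evaluation grid (default
    [100, 1100] µm, 512 points). Returns ``(grid, density)``.
    """
    d = np.asarray(diameters, dtype=float)
    if d.size < 5:
        raise ValueError("need at least 5 diameters for a smoothed OSFD")
    if grid is None:
        grid = np.linspace(MIN_DIAMETER, MAX_DIAMETER, 512)
    if bandwidth is None:
        sigma = float(np.std(d, ddof=1))
        iqr = float(np.subtract(*np.percentile(d, [75, 25])))
        spread = min(sigma, iqr / 1.34) if iqr > 0 else sigma
        # Silverman's rule; a degenerate (zero-spread) sample gets a 10 um kernel
        bandwidth = 0.9 * spread * d.size ** (-0.2) if spread > 0 else 10.0
    if not bandwidth > 0:
        raise ValueError("bandwidth must be positive")
    dens = stats.norm.pdf(grid[:, None], loc=d[None, :], scale=bandwidth).mean(axis=1)
    area = np.trapezoid(dens, grid)
    if area <= 0:
        raise ValueError("density vanished on the evaluation grid")
    return grid, dens / area
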