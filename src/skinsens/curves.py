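"""Concentration-response processing for quantitative HTS assays.

Raw plate signals are normalized to percent activity relative to the
per-run median of the DMSO vehicle-control wells, fitted to a
four-parameter Hill equation, and summarized as a curve class
(quality of the concentration-response relationship), a signed curve
rank in [-9, 9] (0 = inactive, negative = inhibition), and a tri-run
activity outcome.  For the keratinocyte Nrf2/ARE reporter assay the
fold-induction summaries EC1.5 and Imax are derived on the normalized
scale where 0 % is vehicle and 100 % is a two-fold induction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .exceptions import InsufficientDataError, InvalidArgumentError, NormalizationError

__all__ = [
    "ConcentrationResponseSeries",
    "HillFit",
    "CurveClassification",
    "KSActivitySummary",
    "hill_curve",
    "percent_activity",
    "normalize_percent_activity",
    "fit_hill",
    "classify_curve",
    "ks_activity_summary",
    "activity_outcome_across_runs",
    "mask_cytotoxic_points",
    "fit_plate",
]

# Curve-class -> |curve rank| tiers: (|efficacy| >= 80, |efficacy| < 80).
# Classes 1.x have both asymptotes inside the tested range, 2.x lack the
# outer asymptote, 3 responds only at the top concentration, 4 is inactive.
_RANK_TIERS = {1.1: (9, 8), 1.2: (7, 6), 2.1: (5, 4), 2.2: (3, 2)}

MIN_EFFICACY = 30.0  # % activity; below this a fit is treated as inactive
HIGH_QUALITY_R2 = 0.9
HIGH_EFFICACY = 80.0  # % activity; tier break inside each curve class
ASYMPTOTE_TOL = 0.1  # fraction of |efficacy| left uncovered at a range end


@dataclass
class ConcentrationResponseSeries:
    """One compound x one assay readout across a titration, for one run."""

    compound_id: str
    assay_id: str
    concentrations: np.ndarray  # µM, strictly positive, ascending
    activities: np.ndarray  # % activity, finite
    run: int = 0

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.activities = np.asarray(self.activities, dtype=float)
        if self.concentrations.shape != self.activities.shape:
            raise InvalidArgumentError("concentration/activity length mismatch")
        if np.any(self.concentrations <= 0):
            raise InvalidArgumentError("concentrations must be strictly positive")
        if np.any(np.diff(self.concentrations) < 0):
            order = np.argsort(self.concentrations)
            self.concentrations = self.concentrations[order]
            self.activities = self.activities[order]
        if not np.all(np.isfinite(self.activities)):
            raise InvalidArgumentError("activities must be finite")


@dataclass
class HillFit:
    """Four-parameter Hill fit y(x) = S0 + (Sinf - S0) / (1 + (AC50/x)^h)."""

    s0: float  # baseline asymptote, % activity
    sinf: float  # plateau asymptote, % activity
    ac50: float  # half-maximal concentration, µM
    h: float  # Hill coefficient
    r2: float
    converged: bool

    @property
    def efficacy(self) -> float:
        """Signed maximal response Sinf - S0, in % activity."""
        return self.sinf - self.s0

    def predict(self, x: np.ndarray) -> np.ndarray:
        return hill_curve(np.asarray(x, dtype=float), self.s0, self.sinf, self.ac50, self.h)


@dataclass
class CurveClassification:
    curve_class: float  # one of 1.1, 1.2, 2.1, 2.2, 3, 4
    curve_rank: int  # [-9, 9]; 0 iff class 4
    direction: str  # "activation" | "inhibition" | "none"


@dataclass
class KSActivitySummary:
    """KeratinoSens summaries on the 0 % = vehicle / 100 % = 2-fold scale."""

    ec1_5: float | None  # µM where fold induction crosses 1.5 (y = 50 %)
    imax: float  # maximal observed % activity
    imax_fitted: float | None = None  # maximal fitted % activity


def hill_curve(x, s0, sinf, ac50, h):
    """Four-parameter Hill equation."""
    x = np.asarray(x, dtype=float)
    return s0 + (sinf - s0) / (1.0 + (ac50 / x) ** h)


def percent_activity(v, vdmso_median: float):
    """Normalize raw signal to % activity: (V - VDMSO) / VDMSO * 100."""
    if vdmso_median == 0 or not np.isfinite(vdmso_median):
        raise NormalizationError("DMSO median is zero or non-finite")
    return (np.asarray(v, dtype=float) - vdmso_median) / vdmso_median * 100.0


def normalize_percent_activity(
    wells: pd.DataFrame, assay_id: str = "assay"
) -> list[ConcentrationResponseSeries]:
    """Normalize a well table to per-compound percent-activity series.

    ``wells`` has columns compound_id, conc_uM, raw_signal, run, is_control;
    the DMSO median is recomputed per run.  Raises
    :class:`NormalizationError` when a run has no control wells or a zero
    control median.
    """
    required = {"compound_id", "conc_uM", "raw_signal", "run", "is_control"}
    missing = required - set(wells.columns)
    if missing:
        raise InvalidArgumentError(f"well table missing columns: {sorted(missing)}")
    out: list[ConcentrationResponseSeries] = []
    for run, grp in wells.groupby("run", sort=True):
        dmso = grp.loc[grp["is_control"].astype(bool), "raw_signal"]
        if dmso.empty:
            raise NormalizationError(f"run {run} has no DMSO control wells")
        vdmso = float(dmso.median())
        compounds = grp.loc[~grp["is_control"].astype(bool)]
        for cid, series in compounds.groupby("compound_id", sort=True):
            series = series.sort_values("conc_uM")
            out.append(
                ConcentrationResponseSeries(
                    compound_id=str(cid),
                    assay_id=assay_id,
                    concentrations=series["conc_uM"].to_numpy(),
                    activities=percent_activity(series["raw_signal"].to_numpy(), vdmso),
                    run=int(run),
                )
            )
    return out


def _fit_once(x, y, p0, bounds):
    try:
        popt, _ = curve_fit(
            lambda lx, s0, sinf, lac50, h: hill_curve(10.0**lx, s0, sinf, 10.0**lac50, h),
            np.log10(x),
            y,
            p0=p0,
            bounds=bounds,
            maxfev=5000,
        )
    except (RuntimeError, ValueError):
        return None
    resid = y - hill_curve(x, popt[0], popt[1], 10.0 ** popt[2], popt[3])
    return popt, float(np.sum(resid**2))


def fit_hill(series: ConcentrationResponseSeries) -> HillFit:
    """Least-squares four-parameter Hill fit in log-concentration space.

    AC50 is bounded to [min_conc/10, max_conc*10] and the Hill slope to
    [0.3, 8]; three AC50 starting points across the tested range guard
    against local minima.  Requires >= 4 distinct concentrations.
    """
    x = series.concentrations
    y = series.activities
    if len(np.unique(x)) < 4:
        raise InsufficientDataError("Hill fit requires >= 4 distinct concentrations")

    lo, hi = np.log10(x.min() / 10.0), np.log10(x.max() * 10.0)
    span = max(y.max() - y.min(), 1.0)
    s_lo = y.min() - 2.0 * span
    s_hi = y.max() + 2.0 * span
    bounds = ([s_lo, s_lo, lo, 0.3], [s_hi, s_hi, hi, 8.0])

    n_low = max(2, len(x) // 4)
    s0_guess = float(np.median(y[:n_low]))
    sinf_guess = float(np.median(y[-n_low:]))
    best = None
    for lac50 in np.linspace(lo + 0.25 * (hi - lo), hi - 0.25 * (hi - lo), 3):
        res = _fit_once(x, y, [s0_guess, sinf_guess, lac50, 1.0], bounds)
        if res is not None and (best is None or res[1] < best[1]):
            best = res
    if best is None:
        return HillFit(float(np.median(y)), float(np.median(y)), float("nan"), 1.0, 0.0, False)

    popt, sse = best
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 0.0
    return HillFit(float(popt[0]), float(popt[1]), float(10.0 ** popt[2]), float(popt[3]), r2, True)


def classify_curve(fit: HillFit | None, series: ConcentrationResponseSeries) -> CurveClassification:
    """Assign a curve class and signed curve rank.

    Class 4 (rank 0) covers failed fits and |efficacy| < 30 %.  A curve is
    "complete" (class 1) when the fitted response at both range ends is
    within 10 % of |efficacy| of the respective asymptote; class 3 when the
    half-maximal concentration lies beyond the top tested concentration
    (response only at the highest concentration); class 2 otherwise.
    Sub-class .1 requires r^2 >= 0.9 and |efficacy| >= 80 %.
    """
    if fit is None or not fit.converged or abs(fit.efficacy) < MIN_EFFICACY:
        return CurveClassification(4, 0, "none")

    eff = fit.efficacy
    direction = "activation" if eff > 0 else "inhibition"
    xmin, xmax = float(series.concentrations.min()), float(series.concentrations.max())
    y_lo = float(fit.predict(np.array([xmin]))[0])
    y_hi = float(fit.predict(np.array([xmax]))[0])
    frac_low = abs(y_lo - fit.s0) / abs(eff)
    frac_high = abs(fit.sinf - y_hi) / abs(eff)

    high_quality = fit.r2 >= HIGH_QUALITY_R2 and abs(eff) >= HIGH_EFFICACY
    if frac_low <= ASYMPTOTE_TOL and frac_high <= ASYMPTOTE_TOL:
        curve_class = 1.1 if high_quality else 1.2
    elif fit.ac50 >= xmax:
        curve_class = 3
    else:
        curve_class = 2.1 if high_quality else 2.2

    if curve_class == 3:
        magnitude = 1
    else:
        hi_tier, lo_tier = _RANK_TIERS[curve_class]
        magnitude = hi_tier if abs(eff) >= HIGH_EFFICACY else lo_tier
    rank = magnitude if direction == "activation" else -magnitude
    return CurveClassification(curve_class, rank, direction)


def ks_activity_summary(
    fit: HillFit | None, series: ConcentrationResponseSeries
) -> KSActivitySummary:
    """EC1.5 and Imax for the KeratinoSens reporter.

    On the normalized scale, fold(x) = 1 + y(x)/100, so the 1.5-fold
    threshold is y = 50 %.  EC1.5 is the smallest tested concentration at
    which the fitted curve reaches 50 %, absent if the curve never crosses
    inside the tested range.  Imax is the maximal observed % activity
    (100 % corresponds to two-fold of the vehicle control); the fitted
    maximum is reported alongside.
    """
    imax_obs = float(series.activities.max())
    if fit is None or not fit.converged:
        return KSActivitySummary(None, imax_obs, None)

    xmin, xmax = float(series.concentrations.min()), float(series.concentrations.max())
    grid = np.logspace(math.log10(xmin), math.log10(xmax), 256)
    yhat = fit.predict(grid)
    imax_fit = float(yhat.max())

    ec = None
    s0, sinf, h, ac50 = fit.s0, fit.sinf, fit.h, fit.ac50
    if sinf > 50.0 and sinf > s0:  # increasing curve that reaches threshold
        if s0 >= 50.0:
            ec = xmin  # already above threshold at the lowest tested dose
        else:
            ratio = (sinf - 50.0) / (50.0 - s0)
            x_cross = ac50 / ratio ** (1.0 / h)
            if x_cross <= xmax:
                ec = max(x_cross, xmin)
    return KSActivitySummary(ec, imax_obs, imax_fit)


def activity_outcome_across_runs(classifications: list[CurveClassification]) -> str:
    """Tri-run activity outcome: active, inactive, or inconclusive.

    A run is active when |curve rank| > 3.  Active requires >= 2 active
    runs of the same direction; inactive requires >= 2 class-4 runs and no
    high-quality active run; anything else is inconclusive.
    """
    if not classifications:
        raise InvalidArgumentError("at least one run required")
    ranks = [c.curve_rank for c in classifications]
    pos_active = sum(1 for r in ranks if r > 3)
    neg_active = sum(1 for r in ranks if r < -3)
    inactive_runs = sum(1 for c in classifications if c.curve_class == 4)
    if pos_active >= 2 or neg_active >= 2:
        return "active"
    if inactive_runs >= 2 and pos_active == 0 and neg_active == 0:
        return "inactive"
    return "inconclusive"


def mask_cytotoxic_points(
    series: ConcentrationResponseSeries,
    viability: ConcentrationResponseSeries,
    threshold_pct_of_control: float = 70.0,
) -> ConcentrationResponseSeries:
    """Drop reporter points where paired viability falls below threshold.

    Viability is on the same % activity scale (0 % = vehicle), so 70 % of
    control corresponds to -30 % activity.
    """
    cutoff = threshold_pct_of_control - 100.0
    keep = np.ones(len(series.concentrations), dtype=bool)
    for i, c in enumerate(series.concentrations):
        j = np.argmin(np.abs(np.log10(viability.concentrations) - np.log10(c)))
        if viability.activities[j] < cutoff:
            keep[i] = False
    return ConcentrationResponseSeries(
        series.compound_id,
        series.assay_id,
        series.concentrations[keep],
        series.activities[keep],
        series.run,
    )


def fit_plate(wells: pd.DataFrame, assay_id: str = "assay") -> pd.DataFrame:
    """Normalize, fit, classify, and summarize every compound x run.

    Returns the per-compound fit table (one row per compound and run, plus
    a pooled ``outcome`` column from the tri-run rule) with the documented
    column contract used by the TSV writers and the CLI.
    """
    series_list = normalize_percent_activity(wells, assay_id=assay_id)
    rows = []
    per_compound: dict[str, list[CurveClassification]] = {}
    for s in series_list:
        try:
            fit = fit_hill(s)
        except InsufficientDataError:
            fit = None
        cls = classify_curve(fit, s)
        summ = ks_activity_summary(fit, s)
        per_compound.setdefault(s.compound_id, []).append(cls)
        rows.append(
            {
                "compound_id": s.compound_id,
                "assay": assay_id,
                "run": s.run,
                "S0": fit.s0 if fit else np.nan,
                "Sinf": fit.sinf if fit else np.nan,
                "AC50_uM": fit.ac50 if fit else np.nan,
                "hill": fit.h if fit else np.nan,
                "efficacy": fit.efficacy if fit else np.nan,
                "r2": fit.r2 if fit else np.nan,
                "curve_class": cls.curve_class,
                "curve_rank": cls.curve_rank,
                "EC1_5_uM": summ.ec1_5 if summ.ec1_5 is not None else np.nan,
                "Imax_pct": summ.imax,
            }
        )
    df = pd.DataFrame(rows)
    outcomes = {cid: activity_outcome_across_runs(cs) for cid, cs in per_compound.items()}
    df["outcome"] = df["compound_id"].map(outcomes)
    return df
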