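"""Positive/negative assay calls under OECD test-guideline and curve-rank criteria.

Each assay in the skin-sensitization battery has a quantitative readout
and a published decision rule:

* DPRA (protein reactivity): positive when cysteine-peptide depletion
  exceeds 13.89 % or the cysteine/lysine mean depletion exceeds 6.38 %
  (TG 442C); under qHTS curve-rank criteria, depletion is an inhibition-
  mode signal and a rank below -3 is positive.
* KeratinoSens (Nrf2/ARE activation): positive when luciferase induction
  exceeds 1.5-fold of the vehicle control at a non-cytotoxic
  concentration, i.e. EC1.5 exists; curve-rank criterion: rank > 3.
* hCLAT (dendritic-cell activation): positive when CD86 RFI > 1.5 or
  CD54 RFI > 2.0 over vehicle.
* IL-8 release: positive when fold induction >= 1.4 and the lower bound
  of its 95 % confidence interval exceeds 1.0; curve-rank: rank > 3.

TG calls and curve-rank calls are computed independently; their
concordance is an analysis output, never an input.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InvalidArgumentError, MissingDataError

__all__ = [
    "POSITIVE",
    "NEGATIVE",
    "ABSENT",
    "dpra_depletion",
    "dpra_call_tg",
    "dpra_call_curverank",
    "ks_call_tg",
    "activation_call_curverank",
    "hclat_call",
    "hclat_mit",
    "il8_fold_ci",
    "il8_call_tg",
    "call_panel",
]

POSITIVE = "positive"
NEGATIVE = "negative"
ABSENT = "absent"

DPRA_CYS_THRESHOLD = 13.89  # % depletion, cysteine peptide
DPRA_MEAN_THRESHOLD = 6.38  # % depletion, mean of cysteine and lysine
KS_FOLD_THRESHOLD = 1.5
HCLAT_CD86_THRESHOLD = 1.5
HCLAT_CD54_THRESHOLD = 2.0
IL8_FOLD_THRESHOLD = 1.4
CURVE_RANK_THRESHOLD = 3  # strict: rank > 3 (activation) / < -3 (inhibition)


def _is_absent(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return False


def dpra_depletion(sample_ratio: float, control_ratio: float) -> float:
    """Percent peptide depletion from peptide/internal-standard area ratios."""
    if control_ratio is None or control_ratio <= 0:
        raise InvalidArgumentError("control ratio must be positive")
    return (1.0 - sample_ratio / control_ratio) * 100.0


def dpra_call_tg(cys_depletion: float, lys_depletion: float | None = None) -> str:
    """TG 442C call; small negative depletions are clipped to 0 first."""
    if _is_absent(cys_depletion):
        raise MissingDataError("cysteine depletion required for the TG call")
    cys = max(float(cys_depletion), 0.0)
    if cys > DPRA_CYS_THRESHOLD:
        return POSITIVE
    if not _is_absent(lys_depletion):
        lys = max(float(lys_depletion), 0.0)
        if (cys + lys) / 2.0 > DPRA_MEAN_THRESHOLD:
            return POSITIVE
    return NEGATIVE


def dpra_call_curverank(cys_rank: float, lys_rank: float | None = None) -> str:
    """qHTS criterion: depletion is inhibition mode, positive when rank < -3."""
    ranks = [r for r in (cys_rank, lys_rank) if not _is_absent(r)]
    if not ranks:
        raise MissingDataError("no DPRA curve ranks provided")
    return POSITIVE if any(r < -CURVE_RANK_THRESHOLD for r in ranks) else NEGATIVE


def ks_call_tg(ec1_5, imax: float | None = None) -> str:
    """Positive iff induction crossed 1.5-fold at a tested concentration."""
    return POSITIVE if not _is_absent(ec1_5) else NEGATIVE


def activation_call_curverank(curve_rank: float) -> str:
    """Shared by KS and IL-8: positive iff curve rank > 3 (strict)."""
    if _is_absent(curve_rank):
        return ABSENT
    return POSITIVE if curve_rank > CURVE_RANK_THRESHOLD else NEGATIVE


def hclat_call(cd86_rfi: float | None, cd54_rfi: float | None) -> str:
    """Positive iff CD86 RFI > 1.5 or CD54 RFI > 2.0 over vehicle."""
    if _is_absent(cd86_rfi) and _is_absent(cd54_rfi):
        raise MissingDataError("both CD86 and CD54 RFIs absent")
    if not _is_absent(cd86_rfi) and cd86_rfi > HCLAT_CD86_THRESHOLD:
        return POSITIVE
    if not _is_absent(cd54_rfi) and cd54_rfi > HCLAT_CD54_THRESHOLD:
        return POSITIVE
    return NEGATIVE


def hclat_mit(
    concentrations_ugml: np.ndarray, cd86_rfi: np.ndarray, cd54_rfi: np.ndarray
) -> float | None:
    """Minimum induction threshold from a concentration series.

    The lowest tested concentration at which either marker crosses its
    threshold; None when neither ever does.  The single-concentration
    screen design cannot provide this, in which case callers leave MIT
    absent.
    """
    conc = np.asarray(concentrations_ugml, dtype=float)
    order = np.argsort(conc)
    for i in order:
        if cd86_rfi[i] > HCLAT_CD86_THRESHOLD or cd54_rfi[i] > HCLAT_CD54_THRESHOLD:
            return float(conc[i])
    return None


def il8_fold_ci(replicate_folds: np.ndarray, confidence: float = 0.95) -> tuple[float, float]:
    """Mean fold induction and the lower bound of its two-sided t-interval."""
    folds = np.asarray(replicate_folds, dtype=float)
    if folds.size < 2:
        raise InsufficientReplicates("IL-8 CI needs >= 2 replicates")
    mean = float(folds.mean())
    sem = float(folds.std(ddof=1) / math.sqrt(folds.size))
    tcrit = stats.t.ppf(0.5 + confidence / 2.0, folds.size - 1)
    return mean, mean - tcrit * sem


class InsufficientReplicates(MissingDataError):
    """Single replicate: the IL-8 confidence interval is unavailable."""


def il8_call_tg(fold_induction: float, ci95_lower: float) -> str:
    """Positive iff fold >= 1.4 and the 95 % CI lower bound exceeds 1.0."""
    if _is_absent(fold_induction) or _is_absent(ci95_lower):
        raise MissingDataError("IL-8 fold induction and CI lower bound required")
    return POSITIVE if fold_induction >= IL8_FOLD_THRESHOLD and ci95_lower > 1.0 else NEGATIVE


def call_panel(panel: pd.DataFrame) -> pd.DataFrame:
    """Derive per-compound calls from a consolidated assay panel.

    Adds/overwrites ``dpra_call_tg``, ``dpra_call_rank``, ``hclat_call``,
    ``il8_call_tg``, ``ks_call_rank`` columns from the quantitative
    columns when present; missing sources yield ``absent``.  The panel
    column contract is documented in :mod:`skinsens.io`.
    """
    df = panel.copy()

    def _row_dpra_tg(row):
        try:
            return dpra_call_tg(row.get("dpra_cys_pct"), row.get("dpra_lys_pct"))
        except MissingDataError:
            return ABSENT

    def _row_dpra_rank(row):
        try:
            return dpra_call_curverank(row.get("dpra_cys_rank"), row.get("dpra_lys_rank"))
        except MissingDataError:
            return ABSENT

    def _row_hclat(row):
        try:
            return hclat_call(row.get("hclat_cd86_rfi"), row.get("hclat_cd54_rfi"))
        except MissingDataError:
            return ABSENT

    def _row_il8(row):
        try:
            return il8_call_tg(row.get("il8_fold"), row.get("il8_ci_lower"))
        except MissingDataError:
            return ABSENT

    df["dpra_call_tg"] = df.apply(_row_dpra_tg, axis=1)
    if "dpra_cys_rank" in df.columns:
        df["dpra_call_rank"] = df.apply(_row_dpra_rank, axis=1)
    df["hclat_call"] = df.apply(_row_hclat, axis=1)
    df["il8_call_tg"] = df.apply(_row_il8, axis=1)
    if "ks_curve_rank" in df.columns:
        df["ks_call_rank"] = df["ks_curve_rank"].map(activation_call_curverank)
    if "ks_call_tg" not in df.columns and "ks_ec15_uM" in df.columns:
        df["ks_call_tg"] = df["ks_ec15_uM"].map(ks_call_tg)
    return df
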