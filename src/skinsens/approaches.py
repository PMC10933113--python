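"""Defined approaches for skin-sensitization hazard and potency.

Three fixed data-interpretation procedures combine the assay battery:

* **2o3** — hazard call by majority among DPRA, KeratinoSens, and hCLAT.
* **ITSv2** — score-based GHS potency. DPRA depletion and hCLAT MIT are
  binned to 0-3 points each and the in silico hazard prediction adds
  0-1; the total over the available sources maps to GHS 1A / 1B / NC,
  with an inconclusive buffer when sources are missing.
* **STS** — sequential decision tree: hCLAT first (MIT <= 10 µg/mL
  distinguishes 1A from 1B), DPRA second for hCLAT-negative compounds.

GHS categories: 1A = strong sensitizer, 1B = other sensitizer, NC = not
classified.  Concordance analytics (Venn-style positive counts, the
ITS x STS potency contingency, and confusion-matrix statistics between
two call criteria) live here as well.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .calls import ABSENT, NEGATIVE, POSITIVE
from .exceptions import MissingDataError

__all__ = [
    "ITSScore",
    "DAResult",
    "its_dpra_score",
    "its_hclat_score",
    "its_insilico_score",
    "its_score",
    "its_classify",
    "sts_classify",
    "da_2o3",
    "apply_all_das",
    "da_venn",
    "potency_contingency",
    "percent_agreement",
    "binary_agreement_stats",
]

SENSITIZER = "sensitizer"
NON_SENSITIZER = "non-sensitizer"
INCONCLUSIVE = "inconclusive"

# ITS scoring bins (anchored at the TG 442C thresholds 6.38/13.89 and the
# strong-depletion threshold 23.09 quoted for the score-based approach).
DPRA_MEAN_BINS = (6.38, 22.62, 42.47)  # mean(cys, lys) depletion %
DPRA_CYS_ONLY_BINS = (13.89, 23.09, 98.24)  # cysteine-only depletion %
HCLAT_MIT_BINS = (10.0, 150.0, 5000.0)  # µg/mL; lower MIT = higher potency

GHS_ORDER = {"NC": 0, "1B": 1, "1A": 2}


@dataclass
class ITSScore:
    dpra: int | None  # 0-3, None when DPRA absent
    hclat: int | None  # 0-3, None when hCLAT absent
    insilico: int | None  # 0-1, None when absent / out of domain

    @property
    def total(self) -> int:
        return sum(s for s in (self.dpra, self.hclat, self.insilico) if s is not None)

    @property
    def n_sources(self) -> int:
        return sum(s is not None for s in (self.dpra, self.hclat, self.insilico))


@dataclass
class DAResult:
    compound_id: str
    call_2o3: str  # sensitizer / non-sensitizer / inconclusive
    ghs_its: str  # 1A / 1B / NC / inconclusive
    ghs_sts: str  # 1A / 1B / NC / inconclusive
    its: ITSScore | None = None


def _absentish(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    if isinstance(value, str) and value in (ABSENT, "", "out_of_domain"):
        return True
    return False


def its_dpra_score(cys_depletion: float | None, lys_depletion: float | None = None) -> int | None:
    """DPRA potency score 0-3 from peptide depletion.

    Uses the mean-depletion bins when both peptides were measured, the
    cysteine-only bins otherwise; negative depletions clip to 0.
    """
    if _absentish(cys_depletion):
        return None
    cys = max(float(cys_depletion), 0.0)
    if _absentish(lys_depletion):
        value, bins = cys, DPRA_CYS_ONLY_BINS
    else:
        value, bins = (cys + max(float(lys_depletion), 0.0)) / 2.0, DPRA_MEAN_BINS
    if value < bins[0]:
        return 0
    if value < bins[1]:
        return 1
    if value < bins[2]:
        return 2
    return 3


def its_hclat_score(hclat_mit) -> int | None:
    """hCLAT potency score 0-3 from the minimum induction threshold.

    ``hclat_mit`` is the MIT in µg/mL, the string ``"negative"`` for a
    tested-but-negative compound (score 0), or None for an untested /
    absent source.
    """
    if isinstance(hclat_mit, str):
        if hclat_mit == "negative":
            return 0
        return None
    if _absentish(hclat_mit):
        return None
    mit = float(hclat_mit)
    if mit <= HCLAT_MIT_BINS[0]:
        return 3
    if mit <= HCLAT_MIT_BINS[1]:
        return 2
    if mit <= HCLAT_MIT_BINS[2]:
        return 1
    return 0


def its_insilico_score(prediction) -> int | None:
    """In silico hazard prediction: positive = 1, negative = 0, else absent."""
    if _absentish(prediction):
        return None
    if prediction == POSITIVE:
        return 1
    if prediction == NEGATIVE:
        return 0
    return None


def its_score(
    cys_depletion=None, lys_depletion=None, hclat_mit=None, insilico=None
) -> ITSScore:
    """Component and total ITS scores; raises when every source is absent."""
    score = ITSScore(
        dpra=its_dpra_score(cys_depletion, lys_depletion),
        hclat=its_hclat_score(hclat_mit),
        insilico=its_insilico_score(insilico),
    )
    if score.n_sources == 0:
        raise MissingDataError("ITS requires at least one information source")
    return score


def its_classify(score: ITSScore) -> str:
    """Map an ITS score to a GHS category.

    Three sources: 6-7 -> 1A, 2-5 -> 1B, 0-1 -> NC.  Two sources: 6 -> 1A,
    2-5 -> 1B, 1 -> inconclusive, 0 -> NC.  Fewer than two sources cannot
    support a potency call.
    """
    total, n = score.total, score.n_sources
    if n >= 3:
        if total >= 6:
            return "1A"
        if total >= 2:
            return "1B"
        return "NC"
    if n == 2:
        if total >= 6:
            return "1A"
        if total >= 2:
            return "1B"
        if total == 1:
            return INCONCLUSIVE
        return "NC"
    return INCONCLUSIVE


def sts_classify(hclat_call: str, hclat_mit=None, dpra_call: str = ABSENT) -> str:
    """Sequential testing strategy decision tree.

    hCLAT positive: 1A when MIT <= 10 µg/mL, else 1B (MIT unavailable, as
    in a single-concentration screen, defaults to 1B).  hCLAT negative:
    1B when DPRA is positive, NC when DPRA is negative.
    """
    if _absentish(hclat_call):
        raise MissingDataError("STS requires an hCLAT result")
    if hclat_call == POSITIVE:
        if not _absentish(hclat_mit) and not isinstance(hclat_mit, str):
            return "1A" if float(hclat_mit) <= 10.0 else "1B"
        return "1B"
    if _absentish(dpra_call):
        raise MissingDataError("STS requires a DPRA result for hCLAT-negative compounds")
    return "1B" if dpra_call == POSITIVE else "NC"


def da_2o3(dpra_call: str, ks_call: str, hclat_call: str) -> str:
    """Hazard by majority among DPRA, KS, and hCLAT.

    With one source missing, a call is made only when the two present
    sources agree; fewer than two sources raise.
    """
    calls = [c for c in (dpra_call, ks_call, hclat_call) if not _absentish(c)]
    if len(calls) < 2:
        raise MissingDataError("2o3 requires at least two assay results")
    n_pos = sum(c == POSITIVE for c in calls)
    n_neg = sum(c == NEGATIVE for c in calls)
    if n_pos >= 2:
        return SENSITIZER
    if n_neg >= 2:
        return NON_SENSITIZER
    return INCONCLUSIVE


def apply_all_das(panel: pd.DataFrame) -> pd.DataFrame:
    """Run 2o3, ITSv2, and STS over a called assay panel.

    Expects the panel column contract of :func:`skinsens.calls.call_panel`
    (quantitative columns plus derived call columns).  Out-of-domain in
    silico predictions are treated as absent.  Per-compound failures from
    missing sources are recorded as inconclusive rather than raised.
    """
    from .calls import call_panel

    need = {"dpra_call_tg", "hclat_call"}
    if not need.issubset(panel.columns):
        panel = call_panel(panel)

    rows = []
    for _, row in panel.iterrows():
        cid = str(row["compound_id"])
        dpra = row.get("dpra_call_tg", ABSENT)
        ks = row.get("ks_call_tg", ABSENT)
        hclat = row.get("hclat_call", ABSENT)
        mit = row.get("hclat_mit_ugml")
        if _absentish(mit) and hclat == NEGATIVE:
            mit = "negative"
        insilico = row.get("insilico", ABSENT)

        try:
            call_2o3 = da_2o3(dpra, ks, hclat)
        except MissingDataError:
            call_2o3 = INCONCLUSIVE

        try:
            score = its_score(
                cys_depletion=row.get("dpra_cys_pct"),
                lys_depletion=row.get("dpra_lys_pct"),
                hclat_mit=mit if hclat != ABSENT else None,
                insilico=insilico,
            )
            ghs_its = its_classify(score)
        except MissingDataError:
            score = None
            ghs_its = INCONCLUSIVE

        try:
            ghs_sts = sts_classify(hclat, mit, dpra)
        except MissingDataError:
            ghs_sts = INCONCLUSIVE

        rows.append(
            {
                "compound_id": cid,
                "call_2o3": call_2o3,
                "its_dpra_score": score.dpra if score else None,
                "its_hclat_score": score.hclat if score else None,
                "its_insilico_score": score.insilico if score else None,
                "its_total": score.total if score else None,
                "ghs_its": ghs_its,
                "ghs_sts": ghs_sts,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "compound_id",
            "call_2o3",
            "its_dpra_score",
            "its_hclat_score",
            "its_insilico_score",
            "its_total",
            "ghs_its",
            "ghs_sts",
        ],
    )


def _da_positive_flags(results: pd.DataFrame) -> pd.DataFrame:
    """Per-DA positivity: 2o3 sensitizer; ITS/STS class in {1A, 1B}."""
    return pd.DataFrame(
        {
            "2o3": results["call_2o3"] == SENSITIZER,
            "its": results["ghs_its"].isin(["1A", "1B"]),
            "sts": results["ghs_sts"].isin(["1A", "1B"]),
        },
        index=results.index,
    )


def da_venn(results: pd.DataFrame) -> dict:
    """Counts of compounds positive in exactly 3 / at least 2 / at least 1 DA.

    "All negative" counts compounds explicitly negative (non-sensitizer or
    NC) in every DA; compounds with any unresolved (inconclusive) DA and no
    positive are reported separately.
    """
    pos = _da_positive_flags(results)
    n_pos = pos.sum(axis=1)
    neg = pd.DataFrame(
        {
            "2o3": results["call_2o3"] == NON_SENSITIZER,
            "its": results["ghs_its"] == "NC",
            "sts": results["ghs_sts"] == "NC",
        },
        index=results.index,
    )
    all_negative = int((neg.sum(axis=1) == 3).sum())
    total = len(results)
    n_ge1 = int((n_pos >= 1).sum())
    return {
        "n_total": total,
        "n_positive_all3": int((n_pos == 3).sum()),
        "n_positive_ge2": int((n_pos >= 2).sum()),
        "n_positive_ge1": n_ge1,
        "n_negative_all": all_negative,
        "n_unresolved": total - n_ge1 - all_negative,
    }


def potency_contingency(results: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Cross-tabulate ITS x STS GHS categories and the percent agreement.

    Rows are ITS categories (including the inconclusive buffer), columns
    STS categories; agreement is the share of compounds with identical
    GHS categories among all compounds, rounded to an integer percent.
    """
    its_order = ["NC", "1B", INCONCLUSIVE, "1A"]
    sts_order = ["NC", "1B", "1A"]
    table = pd.crosstab(results["ghs_its"], results["ghs_sts"])
    table = table.reindex(index=its_order, columns=sts_order, fill_value=0)
    agreement = percent_agreement(table, n_total=len(results))
    return table, agreement


def percent_agreement(table: pd.DataFrame, n_total: int | None = None) -> int:
    """Percent of identically categorized compounds from a contingency table.

    ``n_total`` overrides the denominator (by default the table's grand
    total), for tables that exclude unresolved compounds from their cells
    but whose agreement is quoted against the full compound set.
    """
    diag = sum(
        int(table.at[lab, lab]) for lab in table.index if lab in table.columns
    )
    denom = int(n_total) if n_total is not None else int(table.to_numpy().sum())
    if denom <= 0:
        raise MissingDataError("empty contingency table")
    return round(100.0 * diag / denom)


@dataclass
class AgreementStats:
    sensitivity: float
    specificity: float
    balanced_accuracy: float
    mcc: float


def binary_agreement_stats(calls_a, calls_b) -> AgreementStats:
    """Confusion-matrix statistics of ``calls_a`` against reference ``calls_b``.

    Inputs are positive/negative call vectors (or booleans); pairs with an
    absent entry on either side are dropped.  Raises when no pairs remain.
    """
    a = pd.Series(list(calls_a))
    b = pd.Series(list(calls_b))
    if len(a) != len(b):
        raise MissingDataError("call vectors differ in length")

    def _to_bool(s):
        return s.map(lambda v: True if v in (POSITIVE, True, 1) else (False if v in (NEGATIVE, False, 0) else None))

    a, b = _to_bool(a), _to_bool(b)
    keep = a.notna() & b.notna()
    a, b = a[keep].astype(bool), b[keep].astype(bool)
    if len(a) == 0:
        raise MissingDataError("no overlapping calls")
    tp = int((a & b).sum())
    tn = int((~a & ~b).sum())
    fp = int((a & ~b).sum())
    fn = int((~a & b).sum())
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    ba = (sens + spec) / 2.0
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / denom if denom else 0.0
    return AgreementStats(sens, spec, ba, mcc)
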