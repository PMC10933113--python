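"""Chemotype-based compound prioritization and activity aggregation.

Compounds carry one or more structural chemotypes; follow-up testing
budgets require a single representative chemotype per compound and a
bounded selection of compounds spread across chemotype clusters.  The
stated preference order picks medium-sized clusters (10-20 members)
first, then clusters with fewer than 10 members, then those with more
than 20.  Selection within clusters favors potency (low AC50) and
efficacy, small clusters (< 3 members) contribute only compounds with
AC50 < 10 µM and efficacy > 50 %, and larger clusters receive larger
quotas.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import InvalidArgumentError
from .synthetic import ChemotypeTable

__all__ = [
    "assign_representative_chemotype",
    "prioritize_compounds",
    "chemotype_activity_matrix",
]

PREFERRED_BAND = (10, 20)  # cluster sizes preferred for representatives
SMALL_CLUSTER_MAX = 2  # clusters this small only pass the potency gate
POTENCY_GATE_AC50 = 10.0  # µM
EFFICACY_GATE = 50.0  # %


def _band(size: int) -> int:
    """Preference band: 0 = size 10-20, 1 = size < 10, 2 = size > 20."""
    if PREFERRED_BAND[0] <= size <= PREFERRED_BAND[1]:
        return 0
    return 1 if size < PREFERRED_BAND[0] else 2


def assign_representative_chemotype(table: ChemotypeTable) -> dict[str, str]:
    """One representative chemotype per compound.

    Among a compound's chemotypes, prefer the band order above; ties
    within a band break by larger cluster size, then lexicographic
    chemotype id.  Deterministic and idempotent.
    """
    sizes = table.cluster_size
    assignment: dict[str, str] = {}
    for cid, cts in table.memberships.items():
        if not cts:
            continue  # unassigned compounds are flagged by omission
        assignment[cid] = min(cts, key=lambda ct: (_band(sizes[ct]), -sizes[ct], ct))
    return assignment


def prioritize_compounds(
    assignments: dict[str, str],
    activity: pd.DataFrame,
    total: int = 288,
) -> list[str]:
    """Select compounds for follow-up across chemotype clusters.

    ``activity`` has columns compound_id, ac50_uM, efficacy_pct.  Within
    each cluster candidates rank by potency (ascending AC50) then by
    efficacy (descending); clusters with <= 2 members contribute only
    members passing AC50 < 10 µM and efficacy > 50 %.  Quotas start at
    one per cluster with candidates and grow proportionally to cluster
    size (largest remainder, capped at each cluster's candidate count)
    until ``total`` compounds are selected or capacity is exhausted.
    """
    if total <= 0:
        raise InvalidArgumentError("total must be positive")
    act = activity.set_index("compound_id")

    clusters: dict[str, list[str]] = {}
    for cid, ct in assignments.items():
        clusters.setdefault(ct, []).append(cid)

    candidates: dict[str, list[str]] = {}
    for ct, members in clusters.items():
        rows = []
        for cid in members:
            if cid not in act.index:
                continue
            ac50 = float(act.at[cid, "ac50_uM"])
            eff = float(act.at[cid, "efficacy_pct"])
            if np.isnan(ac50) or np.isnan(eff):
                continue
            rows.append((ac50, -abs(eff), cid))
        rows.sort()
        if len(members) <= SMALL_CLUSTER_MAX:
            rows = [
                r for r in rows if r[0] < POTENCY_GATE_AC50 and abs(r[1]) > EFFICACY_GATE
            ]
        candidates[ct] = [cid for _, _, cid in rows]

    eligible = {ct: c for ct, c in candidates.items() if c}
    if not eligible:
        return []

    quota = {ct: 1 for ct in eligible}
    capacity = {ct: len(c) for ct, c in eligible.items()}
    allocated = len(eligible)
    sizes = {ct: len(clusters[ct]) for ct in eligible}

    while allocated < total:
        room = {ct: capacity[ct] - quota[ct] for ct in eligible if capacity[ct] > quota[ct]}
        if not room:
            break
        remaining = total - allocated
        size_sum = sum(sizes[ct] for ct in room)
        # proportional shares with largest remainder, capped by room
        shares = {ct: remaining * sizes[ct] / size_sum for ct in room}
        grant = {ct: min(int(shares[ct]), room[ct]) for ct in room}
        granted = sum(grant.values())
        if granted < remaining:
            leftovers = sorted(
                room,
                key=lambda ct: (-(shares[ct] - int(shares[ct])), -sizes[ct], ct),
            )
            for ct in leftovers:
                if granted >= remaining:
                    break
                if grant[ct] < room[ct]:
                    grant[ct] += 1
                    granted += 1
        if granted == 0:
            break
        for ct, g in grant.items():
            quota[ct] += g
        allocated += granted

    selected: list[str] = []
    for ct in sorted(eligible):
        selected.extend(eligible[ct][: quota[ct]])
    if len(selected) > total:  # final trim preserves per-cluster ranking order
        selected = selected[:total]
    return selected


def chemotype_activity_matrix(
    assignments: dict[str, str], curve_ranks: pd.DataFrame
) -> pd.DataFrame:
    """Chemotype x assay matrix of mean curve ranks.

    ``curve_ranks`` is long-form with columns compound_id, assay,
    curve_rank.  Cells are arithmetic means over member compounds;
    mixed-direction cancellation is reported as-is.  Chemotypes with no
    scored members are absent (NaN after pivoting).
    """
    df = curve_ranks.copy()
    df["chemotype_id"] = df["compound_id"].map(assignments)
    df = df.dropna(subset=["chemotype_id"])
    return df.pivot_table(
        index="chemotype_id", columns="assay", values="curve_rank", aggfunc="mean"
    )
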