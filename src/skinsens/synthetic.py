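"""Synthetic inputs with known ground truth for every pipeline stage.

Four generators emulate the study's data streams without any chemistry:

* dose-response plates — four-parameter Hill signals over a 15-point
  log dilution (defaults 0.0028-92 µM, three runs, 16 DMSO vehicle
  wells per run) with Gaussian plate noise on the % activity scale;
* consolidated assay-call panels drawn backwards from the ITS score
  table so that, with no noise, the score-based and sequential defined
  approaches recover the generating GHS category exactly;
* binary fingerprint matrices (729 features by default) with planted
  feature-label enrichment at a stated odds ratio and realistic class
  imbalance (default active fraction 676/6520);
* chemotype membership tables with controlled cluster sizes and
  multiplicity.

All randomness flows from a single integer seed; identical seeds give
identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calls import NEGATIVE, POSITIVE
from .curves import hill_curve
from .exceptions import InvalidArgumentError

__all__ = [
    "GroundTruthRecord",
    "PlateDataset",
    "FingerprintDataset",
    "ChemotypeTable",
    "gen_dose_response_panel",
    "gen_assay_call_panel",
    "gen_fingerprint_dataset",
    "gen_chemotype_assignments",
]

DEFAULT_CONC_RANGE = (0.0028, 92.0)  # µM, the screened titration range
N_TITRATION_POINTS = 15
DMSO_WELLS_PER_RUN = 16
DEFAULT_ACTIVE_FRACTION = 676 / 6520  # screen hit rate of the modeling set
BASELINE_SIGNAL = 1000.0  # arbitrary raw plate units for vehicle wells


@dataclass
class GroundTruthRecord:
    compound_id: str
    true_ghs: str | None = None  # 1A / 1B / NC (panel world)
    true_active: bool | None = None  # dose-response world
    true_hill: tuple[float, float, float, float] | None = None  # (S0, Sinf, AC50, h)
    true_enriched_features: frozenset[int] | None = None  # fingerprint world


@dataclass
class PlateDataset:
    """Well-level raw signals: compound and DMSO-control wells per run."""

    wells: pd.DataFrame  # compound_id, conc_uM, raw_signal, run, is_control
    n_runs: int


@dataclass
class FingerprintDataset:
    """Binary compound x feature matrix with activity labels."""

    matrix: np.ndarray  # (n_compounds, n_features) of 0/1
    labels: np.ndarray  # 1 = active, 0 = inactive
    compound_ids: list[str]
    feature_ids: list[str]
    true_enriched: frozenset[int] = field(default_factory=frozenset)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix, columns=self.feature_ids)
        df.insert(0, "compound_id", self.compound_ids)
        df["label"] = self.labels
        return df


@dataclass
class ChemotypeTable:
    """Compound -> chemotype memberships with realized cluster sizes."""

    memberships: dict[str, set[str]]

    @property
    def cluster_size(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for cts in self.memberships.values():
            for ct in cts:
                sizes[ct] = sizes.get(ct, 0) + 1
        return sizes

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"compound_id": cid, "chemotype_id": ct}
            for cid, cts in sorted(self.memberships.items())
            for ct in sorted(cts)
        ]
        return pd.DataFrame(rows, columns=["compound_id", "chemotype_id"])


def _dilution_series(conc_range: tuple[float, float], n_points: int = N_TITRATION_POINTS):
    lo, hi = conc_range
    if lo <= 0 or hi <= lo:
        raise InvalidArgumentError("concentration range must satisfy 0 < min < max")
    return np.logspace(np.log10(lo), np.log10(hi), n_points)


def gen_dose_response_panel(
    n_compounds: int,
    active_fraction: float = DEFAULT_ACTIVE_FRACTION,
    noise_sd: float = 5.0,
    conc_range: tuple[float, float] = DEFAULT_CONC_RANGE,
    n_runs: int = 3,
    seed: int = 0,
    p_activation: float = 0.7,
) -> tuple[PlateDataset, list[GroundTruthRecord]]:
    """Simulate raw plate wells for a titration screen.

    Exactly ``round(n_compounds * active_fraction)`` compounds are active:
    their signal follows a Hill curve with S0 = 0, |efficacy| drawn in
    [40, 150] % (sign Bernoulli(``p_activation``) for activation), AC50
    log-uniform strictly inside the tested range, and slope in [0.8, 3].
    Inactive compounds and DMSO wells carry baseline plus noise;
    ``noise_sd`` is the Gaussian sd in % activity units.
    """
    if n_compounds <= 0:
        raise InvalidArgumentError("n_compounds must be positive")
    if not 0.0 <= active_fraction <= 1.0:
        raise InvalidArgumentError("active_fraction must lie in [0, 1]")
    if n_runs < 1:
        raise InvalidArgumentError("n_runs must be >= 1")
    rng = np.random.default_rng(seed)
    conc = _dilution_series(conc_range)
    # AC50 strictly inside the tested range, with enough margin (20x from
    # each end) that both asymptotes of the transition are observable
    log_lo, log_hi = np.log10(conc[0] * 20.0), np.log10(conc[-1] / 20.0)

    n_active = round(n_compounds * active_fraction)
    order = rng.permutation(n_compounds)
    active_idx = set(order[:n_active].tolist())

    truth: list[GroundTruthRecord] = []
    frames = []
    params = {}
    for i in range(n_compounds):
        cid = f"C{i:05d}"
        if i in active_idx:
            eff = rng.uniform(40.0, 150.0)
            if rng.random() >= p_activation:
                eff = -eff
            ac50 = 10.0 ** rng.uniform(log_lo, log_hi)
            h = rng.uniform(0.8, 3.0)
            params[cid] = (0.0, eff, ac50, h)
            truth.append(GroundTruthRecord(cid, true_active=True, true_hill=(0.0, eff, ac50, h)))
        else:
            params[cid] = None
            truth.append(GroundTruthRecord(cid, true_active=False, true_hill=None))

    for run in range(n_runs):
        for cid in (f"C{i:05d}" for i in range(n_compounds)):
            p = params[cid]
            y = hill_curve(conc, *p) if p is not None else np.zeros_like(conc)
            if noise_sd > 0:
                y = y + rng.normal(0.0, noise_sd, size=conc.shape)
            frames.append(
                pd.DataFrame(
                    {
                        "compound_id": cid,
                        "conc_uM": conc,
                        "raw_signal": BASELINE_SIGNAL * (1.0 + y / 100.0),
                        "run": run,
                        "is_control": False,
                    }
                )
            )
        ctrl = np.zeros(DMSO_WELLS_PER_RUN)
        if noise_sd > 0:
            ctrl = ctrl + rng.normal(0.0, noise_sd, size=DMSO_WELLS_PER_RUN)
        frames.append(
            pd.DataFrame(
                {
                    "compound_id": "DMSO",
                    "conc_uM": np.nan,
                    "raw_signal": BASELINE_SIGNAL * (1.0 + ctrl / 100.0),
                    "run": run,
                    "is_control": True,
                }
            )
        )
    wells = pd.concat(frames, ignore_index=True)
    return PlateDataset(wells=wells, n_runs=n_runs), truth


# Valid (dpra, hclat, insilico) ITS component decompositions per GHS class,
# constrained so the sequential approach agrees with the generating class:
# 1A needs MIT <= 10 (hclat score 3); 1B needs hclat in {1, 2}, or a
# negative hCLAT with a positive DPRA; NC is negative everywhere.
def _decompositions_1b():
    out = []
    for d in range(4):
        for h in range(3):  # hclat score 3 would be STS 1A
            for s in range(2):
                total = d + h + s
                if not 2 <= total <= 5:
                    continue
                if h == 0 and d == 0:
                    continue  # STS would call NC
                out.append((d, h, s))
    return out


_DECOMP = {
    "1A": [(3, 3, 0), (3, 3, 1), (2, 3, 1)],
    "1B": _decompositions_1b(),
    "NC": [(0, 0, 0)],
}

_DPRA_MEAN_RANGES = ((0.0, 6.0), (6.6, 22.4), (22.8, 42.2), (42.7, 90.0))
_MIT_RANGES = {1: (151.0, 4500.0), 2: (10.5, 150.0), 3: (0.5, 10.0)}


def _draw_source_values(rng, d, h, s, sensitizer: bool) -> dict:
    """Quantitative panel fields consistent with one ITS decomposition."""
    lo, hi = _DPRA_MEAN_RANGES[d]
    dep = rng.uniform(lo, hi)
    row = {"dpra_cys_pct": dep, "dpra_lys_pct": dep}
    if h == 0:
        row.update(
            hclat_cd86_rfi=rng.uniform(0.8, 1.4),
            hclat_cd54_rfi=rng.uniform(0.8, 1.8),
            hclat_mit_ugml=np.nan,
        )
    else:
        lo, hi = _MIT_RANGES[h]
        row.update(
            hclat_cd86_rfi=rng.uniform(1.6, 4.0),
            hclat_cd54_rfi=rng.uniform(1.0, 3.0),
            hclat_mit_ugml=rng.uniform(lo, hi),
        )
    row["insilico"] = POSITIVE if s == 1 else NEGATIVE
    if sensitizer:
        row.update(
            ks_call_tg=POSITIVE,
            ks_ec15_uM=10.0 ** rng.uniform(-1.5, 1.8),
            ks_imax_pct=rng.uniform(60.0, 150.0),
            il8_fold=rng.uniform(1.5, 3.0),
        )
        row["il8_ci_lower"] = rng.uniform(1.05, row["il8_fold"])
    else:
        row.update(
            ks_call_tg=NEGATIVE,
            ks_ec15_uM=np.nan,
            ks_imax_pct=rng.uniform(-10.0, 30.0),
            il8_fold=rng.uniform(0.8, 1.3),
        )
        row["il8_ci_lower"] = row["il8_fold"] - rng.uniform(0.1, 0.3)
    return row


def gen_assay_call_panel(
    n_compounds: int,
    ghs_mix: tuple[float, float, float] = (0.05, 0.45, 0.50),
    missingness: float = 0.0,
    flip_noise: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[GroundTruthRecord]]:
    """Simulate a consolidated assay panel from known GHS ground truth.

    ``ghs_mix`` gives (p_1A, p_1B, p_NC).  Each compound's assay values
    are sampled backwards from the ITS score table inside bins matching
    its class, so at ``flip_noise = 0`` and ``missingness = 0`` both the
    score-based and sequential approaches recover the generating class
    exactly.  ``flip_noise`` independently perturbs each assay source;
    ``missingness`` blanks the in silico prediction (to out-of-domain)
    and the hCLAT source, each with the given probability.
    """
    if n_compounds <= 0:
        raise InvalidArgumentError("n_compounds must be positive")
    if abs(sum(ghs_mix) - 1.0) > 1e-9 or any(p < 0 for p in ghs_mix):
        raise InvalidArgumentError("ghs_mix must be non-negative and sum to 1")
    if not 0.0 <= flip_noise < 0.5:
        raise InvalidArgumentError("flip_noise must lie in [0, 0.5)")
    if not 0.0 <= missingness <= 1.0:
        raise InvalidArgumentError("missingness must lie in [0, 1]")
    rng = np.random.default_rng(seed)

    classes = rng.choice(["1A", "1B", "NC"], size=n_compounds, p=list(ghs_mix))
    rows = []
    truth = []
    for i, ghs in enumerate(classes):
        cid = f"P{i:05d}"
        decomps = _DECOMP[str(ghs)]
        d, h, s = decomps[rng.integers(len(decomps))]
        row = {"compound_id": cid}
        row.update(_draw_source_values(rng, d, h, s, sensitizer=ghs in ("1A", "1B")))

        if flip_noise > 0:
            if rng.random() < flip_noise:  # DPRA: jump to a random other bin
                d2 = int(rng.integers(4))
                lo, hi = _DPRA_MEAN_RANGES[d2]
                dep = rng.uniform(lo, hi)
                row["dpra_cys_pct"] = row["dpra_lys_pct"] = dep
            if rng.random() < flip_noise:  # hCLAT: toggle outcome
                h2 = 0 if h > 0 else int(rng.integers(1, 4))
                tmp = _draw_source_values(rng, 0, h2, 0, sensitizer=h2 > 0)
                for k in ("hclat_cd86_rfi", "hclat_cd54_rfi", "hclat_mit_ugml"):
                    row[k] = tmp[k]
            if rng.random() < flip_noise:  # in silico: flip prediction
                row["insilico"] = NEGATIVE if row["insilico"] == POSITIVE else POSITIVE
            if rng.random() < flip_noise:  # KS: flip call
                if row["ks_call_tg"] == POSITIVE:
                    row.update(ks_call_tg=NEGATIVE, ks_ec15_uM=np.nan)
                else:
                    row.update(ks_call_tg=POSITIVE, ks_ec15_uM=10.0 ** rng.uniform(-1.5, 1.8))
            if rng.random() < flip_noise:  # IL-8: flip call
                if row["il8_fold"] >= 1.4:
                    row["il8_fold"] = rng.uniform(0.8, 1.3)
                    row["il8_ci_lower"] = row["il8_fold"] - 0.2
                else:
                    row["il8_fold"] = rng.uniform(1.5, 3.0)
                    row["il8_ci_lower"] = rng.uniform(1.05, row["il8_fold"])

        if missingness > 0:
            if rng.random() < missingness:
                row["insilico"] = "out_of_domain"
            if rng.random() < missingness:
                row.update(
                    hclat_cd86_rfi=np.nan, hclat_cd54_rfi=np.nan, hclat_mit_ugml=np.nan
                )

        rows.append(row)
        truth.append(GroundTruthRecord(cid, true_ghs=str(ghs)))

    columns = [
        "compound_id",
        "dpra_cys_pct",
        "dpra_lys_pct",
        "ks_call_tg",
        "ks_ec15_uM",
        "ks_imax_pct",
        "hclat_cd86_rfi",
        "hclat_cd54_rfi",
        "hclat_mit_ugml",
        "il8_fold",
        "il8_ci_lower",
        "insilico",
    ]
    return pd.DataFrame(rows, columns=columns), truth


def gen_fingerprint_dataset(
    n_compounds: int,
    n_features: int = 729,
    n_enriched: int = 20,
    odds_ratio: float = 8.0,
    base_prevalence: float = 0.1,
    active_fraction: float = DEFAULT_ACTIVE_FRACTION,
    seed: int = 0,
) -> FingerprintDataset:
    """Binary fingerprints with planted feature-label enrichment.

    Non-enriched features are Bernoulli(``base_prevalence``) in both
    classes; enriched features have their odds multiplied by
    ``odds_ratio`` among actives.  Exactly ``round(n * active_fraction)``
    compounds are active.
    """
    if n_compounds <= 0 or n_features <= 0:
        raise InvalidArgumentError("n_compounds and n_features must be positive")
    if n_enriched > n_features:
        raise InvalidArgumentError("n_enriched cannot exceed n_features")
    if odds_ratio <= 0:
        raise InvalidArgumentError("odds_ratio must be positive")
    if not 0.0 < base_prevalence < 1.0:
        raise InvalidArgumentError("base_prevalence must lie in (0, 1)")
    rng = np.random.default_rng(seed)

    n_active = round(n_compounds * active_fraction)
    labels = np.zeros(n_compounds, dtype=int)
    labels[rng.permutation(n_compounds)[:n_active]] = 1

    enriched = rng.choice(n_features, size=n_enriched, replace=False) if n_enriched else np.array([], dtype=int)
    odds = base_prevalence / (1.0 - base_prevalence)
    p_enriched_active = odds_ratio * odds / (1.0 + odds_ratio * odds)

    p = np.full((n_compounds, n_features), base_prevalence)
    if n_enriched:
        p[np.ix_(labels == 1, enriched)] = p_enriched_active
    matrix = (rng.random((n_compounds, n_features)) < p).astype(np.int8)

    return FingerprintDataset(
        matrix=matrix,
        labels=labels,
        compound_ids=[f"F{i:05d}" for i in range(n_compounds)],
        feature_ids=[f"ct{j:04d}" for j in range(n_features)],
        true_enriched=frozenset(int(j) for j in enriched),
    )


def gen_chemotype_assignments(
    n_compounds: int,
    cluster_size_dist: dict[int, int],
    multiplicity: float = 1.0,
    seed: int = 0,
) -> ChemotypeTable:
    """Chemotype membership table with controlled primary cluster sizes.

    ``cluster_size_dist`` maps cluster size -> number of clusters; the sum
    of size*count must equal ``n_compounds``, and each compound's primary
    cluster realizes those sizes exactly.  ``multiplicity`` > 1 adds
    Poisson(multiplicity - 1) secondary memberships per compound, which
    inflate the realized sizes of the receiving clusters.
    """
    if not cluster_size_dist:
        raise InvalidArgumentError("cluster size distribution must be non-empty")
    if multiplicity < 1.0:
        raise InvalidArgumentError("multiplicity must be >= 1")
    total = sum(size * count for size, count in cluster_size_dist.items())
    if total != n_compounds:
        raise InvalidArgumentError(
            f"cluster sizes sum to {total}, but n_compounds = {n_compounds}"
        )
    rng = np.random.default_rng(seed)

    sizes = []
    for size, count in sorted(cluster_size_dist.items()):
        sizes.extend([size] * count)
    chemotypes = [f"CT{k:04d}" for k in range(len(sizes))]

    order = rng.permutation(n_compounds)
    memberships: dict[str, set[str]] = {}
    pos = 0
    for ct, size in zip(chemotypes, sizes):
        for idx in order[pos : pos + size]:
            memberships[f"C{idx:05d}"] = {ct}
        pos += size

    if multiplicity > 1.0 and len(chemotypes) > 1:
        for cid in sorted(memberships):
            extra = rng.poisson(multiplicity - 1.0)
            if extra:
                others = [ct for ct in chemotypes if ct not in memberships[cid]]
                take = min(extra, len(others))
                picks = rng.choice(len(others), size=take, replace=False)
                memberships[cid].update(others[i] for i in picks)
    return ChemotypeTable(memberships=memberships)
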