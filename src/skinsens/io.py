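"""Delimited-text readers and writers for the pipeline's tables.

All artifacts are plain TSV (comma optional via ``sep``) with stable,
documented headers:

* plate wells: compound_id, conc_uM, raw_signal, run, is_control
* assay panel: compound_id, dpra_cys_pct, dpra_lys_pct, ks_call_tg,
  ks_ec15_uM, ks_imax_pct, hclat_cd86_rfi, hclat_cd54_rfi,
  hclat_mit_ugml, il8_fold, il8_ci_lower, insilico
  (plus derived *_call columns after :func:`skinsens.calls.call_panel`)
* fit table: compound_id, assay, run, S0, Sinf, AC50_uM, hill, efficacy,
  r2, curve_class, curve_rank, EC1_5_uM, Imax_pct, outcome
* defined-approach results: compound_id, call_2o3, its_dpra_score,
  its_hclat_score, its_insilico_score, its_total, ghs_its, ghs_sts
* chemotype memberships: compound_id, chemotype_id
* fingerprints: compound_id, <feature columns>, label
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import ChemotypeTable, FingerprintDataset, PlateDataset

__all__ = [
    "write_plate",
    "read_plate",
    "write_panel",
    "read_panel",
    "write_fingerprints",
    "read_fingerprints",
    "write_chemotypes",
    "read_chemotypes",
    "write_table",
    "write_summary_json",
]


def write_plate(plate: PlateDataset, path, sep: str = "\t") -> None:
    plate.wells.to_csv(path, sep=sep, index=False)


def read_plate(path, sep: str = "\t") -> PlateDataset:
    wells = pd.read_csv(path, sep=sep)
    return PlateDataset(wells=wells, n_runs=int(wells["run"].nunique()))


def write_panel(panel: pd.DataFrame, path, sep: str = "\t") -> None:
    panel.to_csv(path, sep=sep, index=False)


def read_panel(path, sep: str = "\t") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep)


def write_fingerprints(dataset: FingerprintDataset, path, sep: str = "\t") -> None:
    dataset.to_frame().to_csv(path, sep=sep, index=False)


def read_fingerprints(path, sep: str = "\t") -> FingerprintDataset:
    df = pd.read_csv(path, sep=sep)
    feature_cols = [c for c in df.columns if c not in ("compound_id", "label")]
    return FingerprintDataset(
        matrix=df[feature_cols].to_numpy(dtype=np.int8),
        labels=df["label"].to_numpy(dtype=int),
        compound_ids=df["compound_id"].astype(str).tolist(),
        feature_ids=feature_cols,
    )


def write_chemotypes(table: ChemotypeTable, path, sep: str = "\t") -> None:
    table.to_frame().to_csv(path, sep=sep, index=False)


def read_chemotypes(path, sep: str = "\t") -> ChemotypeTable:
    df = pd.read_csv(path, sep=sep)
    memberships: dict[str, set[str]] = {}
    for cid, ct in zip(df["compound_id"].astype(str), df["chemotype_id"].astype(str)):
        memberships.setdefault(cid, set()).add(ct)
    return ChemotypeTable(memberships=memberships)


def write_table(df: pd.DataFrame, path, sep: str = "\t") -> None:
    df.to_csv(path, sep=sep, index=False)


def write_summary_json(summary: dict, path) -> None:
    Path(path).write_text(json.dumps(summary, indent=2, default=_jsonable) + "\n")


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict()
    raise TypeError(f"not JSON serializable: {type(obj)}")
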