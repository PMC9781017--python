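"""Ingestion of external docking score tables; ligand efficiency and LELP.

Docking itself is out of scope: binding energies (dG, kcal/mol) produced
by an external docking program are consumed from a documented CSV
contract.  Two receptor conformations are distinguished: the closed
(antagonist-bound) and open (agonist-bound) states of the channel.

Ligand efficiency uses the positive sign convention LE = -dG / nHeavy so
that favorable binding gives positive LE, and LELP = logP / LE, which
penalizes affinity bought purely with lipophilicity.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .metrics import roc_auc

log = logging.getLogger(__name__)

RECEPTOR_STATES = ("closed_antagonist_bound", "open_agonist_bound")


@dataclass(frozen=True)
class DockingRecord:
    compound_id: str
    receptor_state: str
    deltaG: float                  # kcal/mol, negative for favorable poses
    conformation_rank: int = 1

    def __post_init__(self):
        if self.receptor_state not in RECEPTOR_STATES:
            raise ValueError(f"unknown receptor state {self.receptor_state!r}")
        if self.conformation_rank < 1:
            raise ValueError("conformation_rank must be >= 1")


@dataclass(frozen=True)
class EfficiencyRecord:
    compound_id: str
    LE: float                      # kcal/mol per heavy atom
    LELP: float | None             # None when LE == 0


def read_docking_table(path: str | Path, rank_filter: int | None = 1
                       ) -> list[DockingRecord]:
    """Read a docking score CSV: compound_id, receptor_state, deltaG,
    conformation_rank.  Rank-1 poses are the primary scores; pass
    ``rank_filter=None`` to keep all conformations."""
    df = pd.read_csv(path)
    required = {"compound_id", "receptor_state", "deltaG", "conformation_rank"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    dupes = df.duplicated(subset=["compound_id", "receptor_state", "conformation_rank"])
    if dupes.any():
        offending = df.loc[dupes, ["compound_id", "receptor_state", "conformation_rank"]]
        raise ValueError(f"duplicate (compound, state, rank) rows:\n{offending}")
    n_pos = int((df["deltaG"] > 0).sum())
    if n_pos:
        warnings.warn(f"{n_pos} docking records have positive deltaG (unfavorable); retained")
    if rank_filter is not None:
        df = df[df["conformation_rank"] == rank_filter]
    return [DockingRecord(str(r.compound_id), r.receptor_state, float(r.deltaG),
                          int(r.conformation_rank))
            for r in df.itertuples()]


def ligand_efficiency(deltaG: float, n_heavy: int) -> float:
    """LE = -dG / heavy atoms (positive for favorable binding)."""
    if n_heavy < 1:
        raise ValueError("ligand efficiency requires at least one heavy atom")
    return -deltaG / n_heavy


def lelp(logP: float, LE: float) -> float:
    """LELP = logP / LE; undefined (raises) at LE = 0."""
    if LE == 0:
        raise ZeroDivisionError("LELP undefined at LE = 0")
    return logP / LE


def efficiency_table(records: Sequence[DockingRecord],
                     n_heavy: dict[str, int],
                     logp: dict[str, float]) -> pd.DataFrame:
    """LE and LELP for rank-1 records; compounds with LE = 0 get missing
    LELP and a warning (they are excluded from downstream features)."""
    rows = []
    n_undefined = 0
    for rec in records:
        if rec.conformation_rank != 1:
            continue
        le = ligand_efficiency(rec.deltaG, n_heavy[rec.compound_id])
        if le == 0:
            n_undefined += 1
            rows.append((rec.compound_id, rec.receptor_state, le, np.nan))
        else:
            rows.append((rec.compound_id, rec.receptor_state, le,
                         lelp(logp[rec.compound_id], le)))
    if n_undefined:
        warnings.warn(f"{n_undefined} compounds have LE = 0; LELP reported missing")
    return pd.DataFrame(rows, columns=["compound_id", "receptor_state", "LE", "LELP"])


def enrichment_roc(scores, positives: Sequence[str], negatives: Sequence[str],
                   orientation: str = "lower_better") -> tuple[float, pd.DataFrame]:
    """Enrichment AUC for ranking actives above inactives/decoys.

    ``scores``: mapping compound_id -> score.  ``orientation``:
    "lower_better" for binding energies (more negative ranks actives
    higher), "higher_better" for LELP-style scores.  Ties use midranks.
    Returns (AUC, ROC curve table with fpr/tpr columns).
    """
    if not positives or not negatives:
        raise ValueError("both classes must be nonempty")
    if orientation not in ("lower_better", "higher_better"):
        raise ValueError(f"unknown orientation {orientation!r}")
    ids = list(positives) + list(negatives)
    vals = np.array([scores[i] for i in ids], dtype=float)
    if orientation == "lower_better":
        vals = -vals
    labels = np.array([True] * len(positives) + [False] * len(negatives))
    auc = roc_auc(vals, labels)

    order = np.argsort(-vals, kind="mergesort")
    tp = np.cumsum(labels[order])
    fp = np.cumsum(~labels[order])
    curve = pd.DataFrame({
        "fpr": np.concatenate([[0.0], fp / len(negatives)]),
        "tpr": np.concatenate([[0.0], tp / len(positives)]),
    })
    return auc, curve
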