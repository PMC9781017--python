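"""Descriptor-threshold classification.

A rule set is a list of univariate descriptor cutoffs (e.g. "nX >= 2",
"AMW < 7.25"); a molecule's criteria count is the number of rules it
satisfies, and it is classified positive when the count reaches the
required minimum (5 of 8 for antagonists, 4 of 8 for agonists by
default).  Cutoffs for new rule sets are selected from ROC curves at the
operating point balancing sensitivity and specificity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .metrics import confusion, report, roc_auc

_DIRECTIONS = ("greater", "greater_equal", "less", "equal")


@dataclass(frozen=True)
class CriterionRule:
    descriptor_name: str
    direction: str
    threshold: float

    def __post_init__(self):
        if self.direction not in _DIRECTIONS:
            raise ValueError(f"unknown direction {self.direction!r}")

    def holds(self, value: float) -> bool:
        if self.direction == "greater":
            return value > self.threshold
        if self.direction == "greater_equal":
            return value >= self.threshold
        if self.direction == "less":
            return value < self.threshold
        return value == self.threshold


@dataclass(frozen=True)
class RuleSet:
    target: str
    rules: tuple[CriterionRule, ...]
    min_required: int

    def __post_init__(self):
        if not 1 <= self.min_required <= len(self.rules):
            raise ValueError("min_required out of range")


#: antagonist rule set: secondary-amine E-state sum, secondary-nitrogen
#: distance-edge, electronegative-atom density, >= 2 halogens, complexity,
#: >= 1 six-membered heteroring, > 5 acceptors, electron-poor CH hydrogens
ANTAGONIST_RULES = RuleSet("ANT", (
    CriterionRule("SssNH", "greater", 2.962),
    CriterionRule("MDEN22", "greater", 0.454),
    CriterionRule("ETA_BetaP_s", "greater", 0.638),
    CriterionRule("nX", "greater_equal", 2),
    CriterionRule("fragC", "greater", 172.070),
    CriterionRule("n6HeteroRing", "greater_equal", 1),
    CriterionRule("nHBAcc2", "greater", 5),
    CriterionRule("maxHother", "greater", 0.631),
), min_required=5)

#: agonist rule set: lipophilic (logP > 3.023), sp3-rich, hydroxylated,
#: aliphatic chain >= 3, halogen-free, small pi system, < 3 nitrogens,
#: light average atom
AGONIST_RULES = RuleSet("AG", (
    CriterionRule("XLogP", "greater", 3.023),
    CriterionRule("HybRatio", "greater", 0.383),
    CriterionRule("nsOH", "greater", 0),
    CriterionRule("nAtomLAC", "greater", 2),
    CriterionRule("nX", "equal", 0),
    CriterionRule("nAtomP", "less", 10),
    CriterionRule("nN", "less", 3),
    CriterionRule("AMW", "less", 7.250),
), min_required=4)


def count_satisfied(vec: Mapping[str, float], ruleset: RuleSet) -> int:
    """Number of rules the descriptor vector satisfies."""
    n = 0
    for rule in ruleset.rules:
        if rule.descriptor_name not in vec:
            raise KeyError(f"descriptor {rule.descriptor_name!r} missing from vector")
        if rule.holds(vec[rule.descriptor_name]):
            n += 1
    return n


def classify(vec: Mapping[str, float], ruleset: RuleSet) -> bool:
    return count_satisfied(vec, ruleset) >= ruleset.min_required


def criteria_counts(matrix: pd.DataFrame, ruleset: RuleSet) -> pd.Series:
    """Per-compound satisfied-criteria counts over a descriptor matrix."""
    return matrix.apply(lambda row: count_satisfied(row, ruleset), axis=1)


def select_cutoff(values, labels) -> tuple[float, float, float, float]:
    """ROC-based cutoff with a balanced sensitivity/specificity operating point.

    Scans every threshold midpoint between consecutive distinct values
    (positive direction: value > threshold predicts positive), maximizing
    min(sens, spec); ties broken by maximal Youden's J, then by the
    smaller threshold.  Returns (threshold, sens, spec, auc).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("select_cutoff requires both classes")
    auc = roc_auc(values, labels)
    uniq = np.unique(values)
    cuts = np.concatenate([[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0])
    best = None
    for t in cuts:
        pred = values > t
        rep = report(confusion(pred, labels))
        key = (min(rep.TPR, rep.TNR), rep.TPR + rep.TNR - 1, -t)
        if best is None or key > best[0]:
            best = (key, t, rep.TPR, rep.TNR)
    _, t, sens, spec = best
    return float(t), float(sens), float(spec), float(auc)


def sweep_min_required(matrix: pd.DataFrame, labels, ruleset: RuleSet,
                       min_range: Sequence[int] = range(3, 9)) -> pd.DataFrame:
    """Classification metrics while varying the required criteria count.

    AUC is computed once from the satisfied-count score; ACC/sens/spec/F1
    are evaluated at each minimum in ``min_range``.
    """
    labels = np.asarray(labels, dtype=bool)
    counts = criteria_counts(matrix, ruleset).to_numpy()
    auc = roc_auc(counts, labels)
    rows = []
    for k in min_range:
        rep = report(confusion(counts >= k, labels))
        rows.append((k, rep.ACC, rep.TPR, rep.TNR, rep.F1, auc))
    return pd.DataFrame(rows, columns=["min_required", "ACC", "sens", "spec", "F1", "AUC"]
                        ).set_index("min_required")


def screen_descriptor_candidates(matrix: pd.DataFrame, labels,
                                 auc_floor: float = 0.8,
                                 alpha: float = 0.05,
                                 corr_limit: float = 0.75,
                                 t_test: str = "welch") -> list[str]:
    """Candidate descriptors for threshold rules, ranked by ROC AUC.

    A descriptor survives if (1) a two-sided two-sample t-test between
    classes rejects at ``alpha`` (Welch by default, ``t_test="pooled"``
    for equal variances), (2) its per-descriptor AUC (orientation-
    corrected: max(auc, 1-auc)) clears ``auc_floor``, and (3) it is not
    pairwise Pearson-correlated above ``corr_limit`` with a
    higher-AUC survivor (greedy elimination).
    """
    labels = np.asarray(labels, dtype=bool)
    if matrix.shape[1] < 2:
        raise ValueError("need at least two descriptors")
    survivors: list[tuple[str, float]] = []
    for name in matrix.columns:
        x = matrix[name].to_numpy(dtype=float)
        pos, neg = x[labels], x[~labels]
        if np.std(pos) == 0 and np.std(neg) == 0:
            continue
        _, p = stats.ttest_ind(pos, neg, equal_var=(t_test == "pooled"))
        if not p < alpha:
            continue
        auc = roc_auc(x, labels)
        auc = max(auc, 1 - auc)
        if auc <= auc_floor:
            continue
        survivors.append((name, auc))
    survivors.sort(key=lambda t: (-t[1], t[0]))

    kept: list[str] = []
    for name, _ in survivors:
        x = matrix[name].to_numpy(dtype=float)
        ok = True
        for other in kept:
            r = np.corrcoef(x, matrix[other].to_numpy(dtype=float))[0, 1]
            if abs(r) > corr_limit:
                ok = False
                break
        if ok:
            kept.append(name)
    return kept


# ------------------------------------------------------------- YAML I/O

def ruleset_to_yaml(ruleset: RuleSet, path) -> None:
    data = {
        "target": ruleset.target,
        "min_required": ruleset.min_required,
        "rules": [
            {"descriptor": r.descriptor_name, "direction": r.direction,
             "threshold": float(r.threshold)}
            for r in ruleset.rules
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def ruleset_from_yaml(path) -> RuleSet:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    rules = tuple(CriterionRule(r["descriptor"], r["direction"], float(r["threshold"]))
                  for r in data["rules"])
    return RuleSet(data["target"], rules, int(data["min_required"]))
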