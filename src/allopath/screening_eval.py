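"""Virtual-screening enrichment evaluation: ROC, AUC, rule of five.

Scored ligand tables (lower score = stronger predicted binding, the docking
convention) with binary active/decoy labels are turned into a receiver
operating characteristic curve,

    TPR = TP / (TP + FN),    FPR = FP / (FP + TN),

with one vertex per distinct score value so that tied scores advance both
rates jointly.  The trapezoidal area under the curve equals the
Mann–Whitney probability that a random active outranks a random decoy,
ties credited 1/2 (0.5 = random screening, 1 = perfect separation).

Drug-likeness is checked with the rule of five: MW ≤ 500 g/mol, logP ≤ 5,
N-or-O acceptor count ≤ 10, NH-or-OH donor count ≤ 5, all inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .structure_io import TableSchemaError

__all__ = ["RocCurve", "MoleculeDescriptors", "roc_points", "auc",
           "rule_of_five", "EvaluationError"]


class EvaluationError(ValueError):
    """The score table cannot be evaluated (e.g. one label class only)."""


@dataclass(frozen=True)
class RocCurve:
    """ROC vertices from (0, 0) to (1, 1), with per-threshold counts."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray    # score at each step vertex (NaN at the origin)
    tp: np.ndarray
    fp: np.ndarray
    n_active: int
    n_decoy: int

    def __post_init__(self) -> None:
        assert self.fpr[0] == 0.0 and self.tpr[0] == 0.0
        assert self.fpr[-1] == 1.0 and self.tpr[-1] == 1.0
        assert (np.diff(self.fpr) >= -1e-15).all()
        assert (np.diff(self.tpr) >= -1e-15).all()


def roc_points(scores: pd.DataFrame, higher_better: bool = False) -> RocCurve:
    """Build the ROC curve of an active/decoy score table.

    Ligands are ranked best-first (lowest score first unless
    ``higher_better``); walking down the ranking, each distinct score value
    contributes one vertex, so ties advance TPR and FPR jointly.

    Raises
    ------
    EvaluationError
        If the table lacks actives or decoys.
    """
    for col in ("score", "label"):
        if col not in scores.columns:
            raise TableSchemaError(f"score table missing column {col!r}")
    labels = scores["label"].astype(str).str.strip().str.lower().to_numpy()
    is_active = labels == "active"
    n_act = int(is_active.sum())
    n_dec = int(len(labels) - n_act)
    if n_act == 0 or n_dec == 0:
        raise EvaluationError(
            f"ROC needs both classes: {n_act} actives, {n_dec} decoys")

    s = scores["score"].to_numpy(float)
    ranking = s if higher_better else -s   # larger ranking value = better
    order = np.argsort(-ranking, kind="stable")
    ranked_vals = ranking[order]
    ranked_act = is_active[order]

    # vertex after the last member of each tie group
    boundaries = np.flatnonzero(np.diff(ranked_vals) != 0)
    ends = np.append(boundaries, len(ranked_vals) - 1)
    tp = np.cumsum(ranked_act)[ends]
    fp = (ends + 1) - tp

    tp = np.concatenate([[0], tp])
    fp = np.concatenate([[0], fp])
    thresholds = np.concatenate([[np.nan], ranked_vals[ends]])
    return RocCurve(fpr=fp / n_dec, tpr=tp / n_act, thresholds=thresholds,
                    tp=tp, fp=fp, n_active=n_act, n_decoy=n_dec)


def auc(curve: RocCurve | pd.DataFrame, higher_better: bool = False) -> float:
    """Trapezoidal area under a ROC curve (score table accepted directly).

    Equals the Mann–Whitney estimate of P(active ranked before decoy), with
    tied scores counted 1/2.
    """
    if isinstance(curve, pd.DataFrame):
        curve = roc_points(curve, higher_better=higher_better)
    return float(np.trapezoid(curve.tpr, curve.fpr))


#: The four rule-of-five criteria: (name, descriptor field, inclusive limit).
RO5_CRITERIA = (("MW", "mw", 500.0),
                ("logP", "logp", 5.0),
                ("acceptors", "acceptors", 10),
                ("donors", "donors", 5))


@dataclass(frozen=True)
class MoleculeDescriptors:
    """Physicochemical descriptors of one ligand (computed elsewhere)."""

    mw: float                      # molecular weight, g/mol
    logp: float                    # octanol/water partition coefficient
    acceptors: int                 # H-bond acceptors (N or O count)
    donors: int                    # H-bond donors (NH or OH count)
    logs: float | None = None      # aqueous solubility, carried as metadata
    tpsa: float | None = None      # topological polar surface area, Å²
    name: str = ""

    def __post_init__(self) -> None:
        if self.mw <= 0:
            raise ValueError("molecular weight must be > 0")
        if self.acceptors < 0 or self.donors < 0:
            raise ValueError("H-bond counts must be ≥ 0")


def rule_of_five(descriptors: MoleculeDescriptors | dict,
                 allow_one_violation: bool = False) -> tuple[bool, list[str]]:
    """Lipinski rule-of-five check with inclusive (≤) thresholds.

    Returns ``(passed, violations)``.  By default a molecule passes only
    with zero violations; ``allow_one_violation`` selects the lenient
    variant.  A missing descriptor field raises a schema error naming it.
    """
    if isinstance(descriptors, dict):
        missing = [f for _, f, _ in RO5_CRITERIA if f not in descriptors]
        if missing:
            raise TableSchemaError(f"descriptors missing field(s) {missing}")
        descriptors = MoleculeDescriptors(
            mw=float(descriptors["mw"]), logp=float(descriptors["logp"]),
            acceptors=int(descriptors["acceptors"]),
            donors=int(descriptors["donors"]))
    violations = [name for name, fieldname, limit in RO5_CRITERIA
                  if getattr(descriptors, fieldname) > limit]
    allowed = 1 if allow_one_violation else 0
    return len(violations) <= allowed, violations
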