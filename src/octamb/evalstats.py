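"""Group comparison of ambiguity indices: Mann-Whitney U and ROC/AUC.

Implements the evaluation design for normal-vs-diseased discrimination:
rank-based two-sample tests on ambiguity indices and ROC curves per
layer and overall.  Higher ambiguity is always oriented as "diseased".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from sklearn import metrics as _skm

from .ambiguity import fovea_mask, ascan_entropy, overall_ambiguity_index
from .errors import ValidationError
from .phantom import BOUNDARY_NAMES, N_BOUNDARIES, BScanSample
from .segnet import BoundaryNet, predict_probabilities

__all__ = [
    "MwuResult",
    "RocResult",
    "StudySettings",
    "CohortStudyResult",
    "mann_whitney_u",
    "roc_curve",
    "auc_equivalence_check",
    "run_cohort_study",
]


@dataclass
class MwuResult:
    U: float  # pairs where group_a exceeds group_b, ties counted 1/2
    p_value: float
    n1: int
    n2: int


@dataclass
class RocResult:
    auc: float
    curve: np.ndarray  # (k, 2) ordered (FPR, TPR) points
    n_pos: int
    n_neg: int


def mann_whitney_u(
    group_a: Sequence[float], group_b: Sequence[float]
) -> MwuResult:
    """Two-sided Mann-Whitney U with midrank ties.

    U counts pairs where a > b (ties as 1/2); the p-value uses the
    normal approximation with tie-corrected variance and a continuity
    correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be nonempty")
    n1, n2 = a.size, b.size
    ranks = rankdata(np.concatenate([a, b]))
    r1 = ranks[:n1].sum()
    u = r1 - n1 * (n1 + 1) / 2.0

    n = n1 + n2
    _, counts = np.unique(np.concatenate([a, b]), return_counts=True)
    tie_term = float((counts**3 - counts).sum())
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1))) if n > 1 else 0.0
    mean = n1 * n2 / 2.0
    if var <= 0:
        p = 1.0
    else:
        z = (u - mean - 0.5 * np.sign(u - mean)) / np.sqrt(var)
        p = min(1.0, 2.0 * norm.sf(abs(z)))
    return MwuResult(U=float(u), p_value=float(p), n1=int(n1), n2=int(n2))


def roc_curve(scores: Sequence[float], labels: Sequence[bool]) -> RocResult:
    """ROC over all score thresholds; AUC by trapezoidal integration."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValidationError("scores and labels must be 1-D and equal length")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("ROC requires both classes present")
    fpr, tpr, _ = _skm.roc_curve(y.astype(int), s)
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(
        auc=auc, curve=np.column_stack([fpr, tpr]), n_pos=n_pos, n_neg=n_neg
    )


def auc_equivalence_check(
    scores: Sequence[float], labels: Sequence[bool], tol: float = 1e-10
) -> bool:
    """Assert the ROC-AUC / Mann-Whitney duality AUC = U' / (n1*n2)."""
    y = np.asarray(labels, dtype=bool)
    s = np.asarray(scores, dtype=float)
    auc = roc_curve(s, y).auc
    u_prime = mann_whitney_u(s[y], s[~y]).U
    return bool(abs(auc - u_prime / (y.sum() * (~y).sum())) <= tol)


@dataclass(frozen=True)
class StudySettings:
    log_base: str = "e"
    fovea_mask_halfwidth: int | None = None
    seed: int = 0


@dataclass
class CohortStudyResult:
    table: pd.DataFrame
    overall_roc: RocResult
    overall_mwu: MwuResult
    #: per-layer Amb-I scored against that layer's own abnormality label
    per_layer_roc: list[RocResult | None] = field(default_factory=list)
    per_layer_mwu: list[MwuResult | None] = field(default_factory=list)
    #: per-layer Amb-I scored against the global (any-abnormality) label
    per_layer_roc_global: list[RocResult | None] = field(default_factory=list)


def run_cohort_study(
    samples: Sequence[BScanSample],
    model: BoundaryNet,
    settings: StudySettings = StudySettings(),
) -> CohortStudyResult:
    """Segment a cohort, compute ambiguity indices, compare groups.

    Produces the per-sample index table plus overall and per-layer
    ROC/AUC and Mann-Whitney results.  Per-layer statistics against the
    layer's own label are ``None`` when that layer has a single class.
    """
    if not getattr(model, "trained", False):
        raise ValidationError("run_cohort_study requires a trained model")
    if not samples:
        raise ValidationError("empty cohort")

    mask = None
    if settings.fovea_mask_halfwidth is not None:
        mask = fovea_mask(
            samples[0].image.shape[1], settings.fovea_mask_halfwidth
        )

    rows = []
    for i, s in enumerate(samples):
        pv = predict_probabilities(model, s.image)
        ep = ascan_entropy(pv, log_base=settings.log_base)
        ai = overall_ambiguity_index(ep, mask=mask)
        row: dict = {"sample_id": i, "overall_amb": ai.overall}
        for l, name in enumerate(BOUNDARY_NAMES):
            row[f"amb_{l}"] = float(ai.per_layer[l])
            row[f"label_{l}"] = bool(s.layer_labels[l])
        row["global_label"] = s.global_label
        rows.append(row)
    table = pd.DataFrame(rows)

    y_global = table["global_label"].to_numpy(dtype=bool)
    if y_global.all() or not y_global.any():
        raise ValidationError("cohort must contain both classes")
    overall = table["overall_amb"].to_numpy()
    overall_roc = roc_curve(overall, y_global)
    overall_mwu = mann_whitney_u(overall[y_global], overall[~y_global])

    per_roc: list[RocResult | None] = []
    per_mwu: list[MwuResult | None] = []
    per_roc_global: list[RocResult | None] = []
    for l in range(N_BOUNDARIES):
        amb = table[f"amb_{l}"].to_numpy()
        y_l = table[f"label_{l}"].to_numpy(dtype=bool)
        if y_l.any() and not y_l.all():
            per_roc.append(roc_curve(amb, y_l))
            per_mwu.append(mann_whitney_u(amb[y_l], amb[~y_l]))
        else:
            per_roc.append(None)
            per_mwu.append(None)
        per_roc_global.append(roc_curve(amb, y_global))

    return CohortStudyResult(
        table=table,
        overall_roc=overall_roc,
        overall_mwu=overall_mwu,
        per_layer_roc=per_roc,
        per_layer_mwu=per_mwu,
        per_layer_roc_global=per_roc_global,
    )
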