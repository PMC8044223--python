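"""Ceiling-normalized top-L precision and Jaccard distances.

Because no negative predictions are made, contact accuracy reduces to
precision TP/(TP+FP) over the selected top-L pairs of each separation
class.  A target-class with fewer than L true contacts caps the achievable
precision at n_true/L, so raw precision is divided by the ceiling
min(1, n_true/L), giving a score on 0–1; equivalently the normalized score
is TP / min(L, n_true).  A target-class with no true contacts is skipped
in averages rather than scored 0 or 1.

Method-level aggregation is macro: per-class accuracy is averaged over
targets first, then the class means are averaged into the overall score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .contact_io import CLASSES, ContactProbMap, ContactSet, top_L
from .errors import InvalidInputError
from .labels import LabelSet

__all__ = [
    "ClassScore",
    "EvaluationResult",
    "raw_precision",
    "normalized_accuracy",
    "evaluate_map",
    "aggregate",
    "jaccard_distance",
    "jaccard_table",
]


@dataclass(frozen=True)
class ClassScore:
    """Scores of one method on one target in one separation class."""

    tp: int
    fp: int
    n_selected: int
    n_true: int
    cap: int  # min(L, n_true): the most true positives top-L can contain
    raw_precision: float
    ceiling: float
    normalized: float | None  # None when n_true == 0 (undefined, skipped)


@dataclass
class EvaluationResult:
    """Per-class scores for one method on one target."""

    target_id: str
    per_class: dict[str, ClassScore]

    @property
    def overall(self) -> float | None:
        """Mean of the defined per-class normalized accuracies."""
        vals = [s.normalized for s in self.per_class.values() if s.normalized is not None]
        return float(np.mean(vals)) if vals else None


def raw_precision(
    predicted: ContactSet, labels: LabelSet, cls: str
) -> tuple[int, int, float]:
    """TP, FP and precision of a predicted contact set against the labels.

    Predicted pairs that cannot be verified (either residue unresolved in
    the structure) are removed before counting, so they are neither TP nor
    FP.  Precision is 0 when nothing verifiable was predicted.
    """
    for pair, pcls in predicted.class_of_pair.items():
        if pcls != cls:
            raise InvalidInputError(
                f"{predicted.target_id}: pair {pair} has class {pcls!r}, expected {cls!r}"
            )
    resolved = labels.resolved
    verifiable = {
        (i, j) for (i, j) in predicted.pairs if resolved[i - 1, j - 1]
    }
    true_cls = labels.true_contacts.pairs_in_class(cls)
    tp = len(verifiable & true_cls)
    fp = len(verifiable) - tp
    precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    return tp, fp, precision


def normalized_accuracy(
    tp: int, n_selected: int, n_true: int, L: int
) -> float | None:
    """Top-L precision divided by the ceiling min(1, n_true/L).

    Simplifies to TP / min(L, n_true).  Undefined (None) when the class has
    no true contacts; such target-classes are skipped when averaging.
    """
    if n_true == 0:
        return None
    return tp / min(L, n_true)


def evaluate_map(
    cmap: ContactProbMap, labels: LabelSet, L: int | None = None
) -> EvaluationResult:
    """Score a probability map against labels with top-L selection per class.

    Pairs touching unresolved residues are dropped *before* selection, so a
    method is never charged for pairs that cannot be checked.  ``L``
    defaults to the target sequence length from the labels.
    """
    if L is None:
        L = labels.L
    if cmap.L != labels.L:
        raise InvalidInputError(
            f"{cmap.target_id}: map has L={cmap.L} but labels have L={labels.L}"
        )
    per_class: dict[str, ClassScore] = {}
    resolved = labels.resolved
    for cls in CLASSES:
        selected = top_L(cmap, L, cls, eligible=resolved)
        tp, fp, prec = raw_precision(selected, labels, cls)
        n_true = labels.n_true_per_class[cls]
        ceiling = min(1.0, n_true / L)
        per_class[cls] = ClassScore(
            tp=tp,
            fp=fp,
            n_selected=len(selected),
            n_true=n_true,
            cap=min(L, n_true),
            raw_precision=prec,
            ceiling=ceiling,
            normalized=normalized_accuracy(tp, len(selected), n_true, L),
        )
    return EvaluationResult(target_id=cmap.target_id, per_class=per_class)


def aggregate(
    results: Sequence[EvaluationResult], micro: bool = False
) -> pd.Series:
    """Summarize one method over many targets.

    Macro (default): average each class's normalized accuracy over the
    targets where it is defined, then average the three class means into
    ``overall``.  Micro pools TP and min(L, n_true) counts over targets
    before dividing — exposed for comparison only.
    """
    if not results:
        raise InvalidInputError("aggregate: no evaluation results")
    out: dict[str, float] = {}
    defined_any = False
    for cls in CLASSES:
        if micro:
            scores = [r.per_class[cls] for r in results if r.per_class[cls].normalized is not None]
            tp_sum = sum(s.tp for s in scores)
            cap_sum = sum(s.cap for s in scores)
            out[cls] = tp_sum / cap_sum if cap_sum else np.nan
        else:
            vals = [
                r.per_class[cls].normalized
                for r in results
                if r.per_class[cls].normalized is not None
            ]
            out[cls] = float(np.mean(vals)) if vals else np.nan
        if np.isfinite(out[cls]):
            defined_any = True
    if not defined_any:
        raise InvalidInputError("aggregate: no target-class has any true contacts")
    class_means = [out[cls] for cls in CLASSES if np.isfinite(out[cls])]
    out["overall"] = float(np.mean(class_means))
    return pd.Series(out)


def jaccard_distance(
    a: ContactSet, b: ContactSet, cls: str | None = None
) -> float:
    """Jaccard distance (|A∪B| − |A∩B|) / |A∪B| between two contact sets.

    0 for identical sets, 1 for disjoint nonempty sets, defined as 0 when
    both sets are empty.  With ``cls`` the sets are first restricted to one
    separation class.
    """
    if a.target_id != b.target_id:
        raise InvalidInputError(
            f"jaccard_distance across targets: {a.target_id!r} vs {b.target_id!r}"
        )
    pa = a.pairs_in_class(cls) if cls else a.pairs
    pb = b.pairs_in_class(cls) if cls else b.pairs
    union = len(pa | pb)
    if union == 0:
        return 0.0
    return (union - len(pa & pb)) / union


def jaccard_table(
    method_sets: Mapping[str, Mapping[str, ContactSet]],
) -> pd.DataFrame:
    """Pairwise per-class Jaccard distances averaged over shared targets.

    ``method_sets[method][target]`` holds that method's union-of-class
    top-L contact set for a target.  Rows: method pairs; columns: the
    three classes plus their unweighted mean (``average``).
    """
    methods = sorted(method_sets)
    rows = []
    for idx, m1 in enumerate(methods):
        for m2 in methods[idx + 1 :]:
            shared = sorted(set(method_sets[m1]) & set(method_sets[m2]))
            if not shared:
                continue
            row: dict[str, object] = {"method_a": m1, "method_b": m2}
            class_means = []
            for cls in CLASSES:
                vals = [
                    jaccard_distance(method_sets[m1][t], method_sets[m2][t], cls)
                    for t in shared
                ]
                row[cls] = float(np.mean(vals))
                class_means.append(row[cls])
            row["average"] = float(np.mean(class_means))
            rows.append(row)
    return pd.DataFrame(rows)
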