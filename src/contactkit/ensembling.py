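"""Ensembling of contact-probability maps.

An ensemble here is the per-pair arithmetic mean of contact probabilities
across prediction methods: averaging boosts pairs the members agree on and
downweighs contacts only a single method proposes.  Sub-ensembles of the
best-ranked members (e.g. the top 20% of methods by overall accuracy) are
built with a ceiling rule on the member count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .contact_io import ContactProbMap
from .errors import InvalidInputError

ZERO_FILL = "zero_fill"
AVERAGE_AVAILABLE = "average_available"
POLICIES = (ZERO_FILL, AVERAGE_AVAILABLE)

__all__ = [
    "ZERO_FILL",
    "AVERAGE_AVAILABLE",
    "POLICIES",
    "EnsembleSpec",
    "ensemble_mean",
    "rank_methods",
    "select_top_fraction",
]


@dataclass(frozen=True)
class EnsembleSpec:
    """Named recipe for an ensemble: members and missing-pair policy.

    ``zero_fill`` treats a pair absent from a member's file as probability 0
    (RR submissions list only confident pairs); ``average_available``
    divides by the number of members actually reporting the pair, for
    distogram-derived maps where every pair is defined.
    """

    name: str
    member_ids: tuple[str, ...]
    missing_pair_policy: str = ZERO_FILL

    def __post_init__(self) -> None:
        if not self.member_ids:
            raise InvalidInputError(f"ensemble {self.name!r}: needs at least one member")
        if len(set(self.member_ids)) != len(self.member_ids):
            raise InvalidInputError(f"ensemble {self.name!r}: duplicate member ids")
        if self.missing_pair_policy not in POLICIES:
            raise InvalidInputError(
                f"ensemble {self.name!r}: unknown policy {self.missing_pair_policy!r}"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "EnsembleSpec":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(
            name=data["name"],
            member_ids=tuple(data["members"]),
            missing_pair_policy=data.get("missing_pair_policy", ZERO_FILL),
        )

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "name": self.name,
                    "members": list(self.member_ids),
                    "missing_pair_policy": self.missing_pair_policy,
                },
                fh,
            )


def ensemble_mean(
    members: Sequence[ContactProbMap], policy: str = ZERO_FILL
) -> ContactProbMap:
    """Per-pair arithmetic mean of the members' contact probabilities.

    With ``average_available`` the denominator is the number of members
    reporting the pair (probability > 0); pairs no member reports stay 0.
    """
    if not members:
        raise InvalidInputError("ensemble_mean needs at least one member map")
    if policy not in POLICIES:
        raise InvalidInputError(f"unknown missing-pair policy {policy!r}")
    L = members[0].L
    target_id = members[0].target_id
    for m in members[1:]:
        if m.L != L:
            raise InvalidInputError(
                f"member length mismatch: {m.target_id} has L={m.L}, expected {L}"
            )
        if m.target_id != target_id:
            raise InvalidInputError(
                f"member target mismatch: {m.target_id!r} vs {target_id!r}"
            )
    stack = np.stack([m.p for m in members])
    if policy == ZERO_FILL:
        p = stack.mean(axis=0)
    else:
        counts = (stack > 0).sum(axis=0)
        p = np.where(counts > 0, stack.sum(axis=0) / np.maximum(counts, 1), 0.0)
    sequence = next((m.sequence for m in members if m.sequence), None)
    return ContactProbMap(target_id=target_id, p=p, sequence=sequence)


def rank_methods(overall_accuracy: Mapping[str, float]) -> list[str]:
    """Order method ids by descending overall accuracy, ties by id ascending."""
    for mid, acc in overall_accuracy.items():
        if not math.isfinite(acc):
            raise InvalidInputError(f"method {mid!r} has non-finite accuracy {acc}")
    return sorted(overall_accuracy, key=lambda mid: (-overall_accuracy[mid], mid))


def select_top_fraction(ranked: Sequence[str], fraction: float) -> list[str]:
    """First ceil(fraction × n) methods of a ranked list (e.g. top 20%).

    Ceiling is the rounding under which the top 20% of 33 methods is 7.
    """
    if not ranked:
        raise InvalidInputError("select_top_fraction: empty method list")
    if not 0 < fraction <= 1:
        raise InvalidInputError(f"fraction must be in (0, 1], got {fraction}")
    return list(ranked[: math.ceil(fraction * len(ranked))])
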