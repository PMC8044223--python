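"""Contact-probability maps, CASP RR files, separation classes, top-L selection.

Residue indices are 1-based everywhere at the API surface (the RR-format
convention) and converted to 0-based array indices only inside this module.
Sequence-separation classes follow the community definition: short = 6–11,
mid = 12–23, long = ≥ 24 residues apart; pairs closer than 6 are excluded
from evaluation altogether.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from Bio import SeqIO

from .errors import InvalidInputError, RRParseError

SHORT = "short"
MID = "mid"
LONG = "long"
EXCLUDED = "excluded"
CLASSES = (SHORT, MID, LONG)

MIN_SEPARATION = 6  # pairs closer in sequence than this are never evaluated

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")

__all__ = [
    "SHORT",
    "MID",
    "LONG",
    "EXCLUDED",
    "CLASSES",
    "MIN_SEPARATION",
    "TargetRecord",
    "ContactProbMap",
    "ContactSet",
    "separation_class",
    "top_L",
    "read_rr",
    "write_rr",
    "read_fasta",
    "contact_set_to_csv",
]


@dataclass(frozen=True)
class TargetRecord:
    """A prediction target: an identifier and its full amino-acid sequence.

    ``L`` is the length of the *sequence the predictors received*, not the
    number of residues resolved in any structure; top-L selection uses it.
    """

    target_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise InvalidInputError(f"{self.target_id}: empty sequence")
        bad = set(self.sequence.upper()) - AA_ALPHABET
        if bad:
            raise InvalidInputError(
                f"{self.target_id}: sequence contains non-amino-acid letters {sorted(bad)}"
            )
        object.__setattr__(self, "sequence", self.sequence.upper())

    @property
    def L(self) -> int:
        return len(self.sequence)


@dataclass
class ContactProbMap:
    """Symmetric L×L matrix of per-pair contact probabilities.

    Pairs never reported by a method hold probability 0 (RR submissions list
    only confident pairs, and the ensemble mean needs a defined value).
    """

    target_id: str
    p: np.ndarray
    sequence: str | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if p.ndim != 2 or p.shape[0] != p.shape[1]:
            raise InvalidInputError(f"{self.target_id}: probability matrix must be square")
        if p.size and (p.min() < 0 or p.max() > 1):
            raise InvalidInputError(
                f"{self.target_id}: probabilities outside [0,1] "
                f"(range {p.min():.4g}..{p.max():.4g})"
            )
        if not np.allclose(p, p.T):
            raise InvalidInputError(f"{self.target_id}: probability matrix not symmetric")
        np.fill_diagonal(p, 0.0)
        self.p = p

    @property
    def L(self) -> int:
        return self.p.shape[0]

    def __getitem__(self, pair: tuple[int, int]) -> float:
        i, j = pair
        return float(self.p[i - 1, j - 1])


@dataclass
class ContactSet:
    """A finite set of residue pairs declared in contact.

    Pairs are (i, j) with i < j, 1-based; every pair has sequence
    separation ≥ 6 and carries its separation class.
    """

    target_id: str
    pairs: frozenset[tuple[int, int]]
    class_of_pair: dict[tuple[int, int], str] = field(default_factory=dict)
    prob_of_pair: dict[tuple[int, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        pairs = frozenset((min(i, j), max(i, j)) for i, j in self.pairs)
        object.__setattr__(self, "pairs", pairs)
        for i, j in pairs:
            cls = separation_class(i, j)
            if cls == EXCLUDED:
                raise InvalidInputError(
                    f"{self.target_id}: pair ({i},{j}) has separation {j - i} < {MIN_SEPARATION}"
                )
            stored = self.class_of_pair.setdefault((i, j), cls)
            if stored != cls:
                raise InvalidInputError(
                    f"{self.target_id}: pair ({i},{j}) tagged {stored!r} but separation says {cls!r}"
                )

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair: tuple[int, int]) -> bool:
        i, j = pair
        return (min(i, j), max(i, j)) in self.pairs

    def pairs_in_class(self, cls: str) -> frozenset[tuple[int, int]]:
        return frozenset(p for p in self.pairs if self.class_of_pair[p] == cls)

    def restrict(self, cls: str) -> "ContactSet":
        sub = self.pairs_in_class(cls)
        return ContactSet(
            target_id=self.target_id,
            pairs=sub,
            class_of_pair={p: cls for p in sub},
            prob_of_pair={p: self.prob_of_pair[p] for p in sub if p in self.prob_of_pair},
        )


def separation_class(i: int, j: int) -> str:
    """Classify a residue pair by sequence separation |i−j|.

    Returns ``"excluded"`` below separation 6, ``"short"`` for 6–11,
    ``"mid"`` for 12–23 and ``"long"`` for ≥ 24.
    """
    if i == j:
        raise InvalidInputError(f"self-pair ({i},{i}) has no separation class")
    s = abs(i - j)
    if s < MIN_SEPARATION:
        return EXCLUDED
    if s <= 11:
        return SHORT
    if s <= 23:
        return MID
    return LONG


def _class_pair_indices(L: int, cls: str) -> tuple[np.ndarray, np.ndarray]:
    """0-based upper-triangle indices of all pairs in a separation class."""
    iu, ju = np.triu_indices(L, k=MIN_SEPARATION)
    s = ju - iu
    if cls == SHORT:
        mask = s <= 11
    elif cls == MID:
        mask = (s >= 12) & (s <= 23)
    elif cls == LONG:
        mask = s >= 24
    else:
        raise InvalidInputError(f"cannot select pairs of class {cls!r}")
    return iu[mask], ju[mask]


def top_L(
    cmap: ContactProbMap,
    L: int,
    cls: str,
    eligible: np.ndarray | None = None,
) -> ContactSet:
    """Select the ``L`` most probable pairs of one separation class.

    Ties break deterministically: higher probability first, then smaller i,
    then smaller j.  If fewer than ``L`` eligible pairs exist, all are
    returned.  ``eligible`` is an optional boolean L×L mask restricting the
    candidate pairs (used to drop pairs that cannot be verified against the
    structure before selection).
    """
    if L < 1:
        raise InvalidInputError(f"L must be >= 1, got {L}")
    iu, ju = _class_pair_indices(cmap.L, cls)
    if eligible is not None:
        keep = eligible[iu, ju]
        iu, ju = iu[keep], ju[keep]
    probs = cmap.p[iu, ju]
    # lexsort: last key is primary
    order = np.lexsort((ju, iu, -probs))[: min(L, len(iu))]
    pairs = {(int(iu[k]) + 1, int(ju[k]) + 1) for k in order}
    return ContactSet(
        target_id=cmap.target_id,
        pairs=frozenset(pairs),
        class_of_pair={p: cls for p in pairs},
        prob_of_pair={(int(iu[k]) + 1, int(ju[k]) + 1): float(probs[k]) for k in order},
    )


# --- CASP RR format -------------------------------------------------------

_HEADER_KEYWORDS = ("PFRMAT", "TARGET", "AUTHOR", "REMARK", "METHOD", "MODEL", "END", "TER")


def read_rr(path: str | Path, length: int | None = None) -> ContactProbMap:
    """Parse a CASP RR contact-prediction file into a :class:`ContactProbMap`.

    Records are ``i j d_low d_high probability`` (the bare ``i j probability``
    variant is also accepted).  Sequence lines between the header and the
    records are concatenated to give the target length; otherwise ``length``
    or the largest residue index seen is used.  Unlisted pairs get
    probability 0.
    """
    path = Path(path)
    target_id = path.stem
    seq_parts: list[str] = []
    records: dict[tuple[int, int], float] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            keyword = line.split(None, 1)[0].upper()
            if keyword in _HEADER_KEYWORDS:
                if keyword == "TARGET" and len(line.split()) > 1:
                    target_id = line.split()[1]
                continue
            fields = line.split()
            if len(fields) == 1 and set(fields[0].upper()) <= AA_ALPHABET:
                seq_parts.append(fields[0].upper())
                continue
            if len(fields) not in (3, 5):
                raise RRParseError(f"{path}:{lineno}: unrecognized line {line!r}")
            try:
                i, j = int(fields[0]), int(fields[1])
                prob = float(fields[-1])
            except ValueError:
                raise RRParseError(f"{path}:{lineno}: malformed record {line!r}") from None
            if i == j:
                raise RRParseError(f"{path}:{lineno}: self-contact ({i},{j})")
            if i < 1 or j < 1:
                raise RRParseError(f"{path}:{lineno}: residue index out of range in {line!r}")
            if not 0.0 <= prob <= 1.0:
                raise RRParseError(f"{path}:{lineno}: probability {prob} outside [0,1]")
            key = (min(i, j), max(i, j))
            if key in records and records[key] != prob:
                raise RRParseError(
                    f"{path}:{lineno}: duplicate pair {key} with conflicting probability"
                )
            records[key] = prob

    sequence = "".join(seq_parts) or None
    if sequence is not None:
        L = len(sequence)
    elif length is not None:
        L = length
    elif records:
        L = max(j for _, j in records)
    else:
        raise RRParseError(f"{path}: no sequence, no records and no length given")
    for i, j in records:
        if j > L:
            raise RRParseError(f"{path}: pair ({i},{j}) exceeds target length {L}")
    p = np.zeros((L, L))
    for (i, j), prob in records.items():
        p[i - 1, j - 1] = p[j - 1, i - 1] = prob
    return ContactProbMap(target_id=target_id, p=p, sequence=sequence)


def write_rr(cmap: ContactProbMap, path: str | Path, min_prob: float = 0.0) -> None:
    """Write a map as a CASP RR file.

    Emits every pair with probability ≥ ``min_prob`` (i < j), sorted by
    descending probability then ascending (i, j), probabilities with six
    decimals.  When ``min_prob`` is 0 only strictly positive pairs are
    written (a zero record carries no information and RR files list
    confident pairs only).
    """
    iu, ju = np.triu_indices(cmap.L, k=1)
    probs = cmap.p[iu, ju]
    keep = probs >= min_prob if min_prob > 0 else probs > 0
    iu, ju, probs = iu[keep], ju[keep], probs[keep]
    order = np.lexsort((ju, iu, -probs))
    with open(path, "w") as fh:
        fh.write("PFRMAT RR\n")
        fh.write(f"TARGET {cmap.target_id}\n")
        fh.write("MODEL 1\n")
        if cmap.sequence:
            for k in range(0, len(cmap.sequence), 50):
                fh.write(cmap.sequence[k : k + 50] + "\n")
        for k in order:
            fh.write(f"{iu[k] + 1} {ju[k] + 1} 0 8 {probs[k]:.6f}\n")
        fh.write("END\n")


def read_fasta(path: str | Path) -> list[TargetRecord]:
    """Read target sequences from a FASTA file."""
    return [
        TargetRecord(target_id=rec.id, sequence=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def contact_set_to_csv(
    sets: Iterable[ContactSet] | ContactSet, path: str | Path
) -> None:
    """Export contact sets as CSV rows (target_id, i, j, class, probability)."""
    if isinstance(sets, ContactSet):
        sets = [sets]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["target_id", "i", "j", "class", "probability"])
        for cset in sets:
            for i, j in sorted(cset.pairs):
                prob = cset.prob_of_pair.get((i, j), "")
                writer.writerow([cset.target_id, i, j, cset.class_of_pair[(i, j)], prob])
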