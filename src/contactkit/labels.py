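"""Ground-truth contact labels derived from experimental structures.

The label pipeline: read a (possibly multi-MODEL) PDB file, take the
representative atom of each residue (Cβ, or Cα for glycine), drop residues
whose amino acid disagrees with the target sequence at their position,
compute the pairwise distance matrix — averaged over models for NMR
ensembles — and call every resolved pair with sequence separation ≥ 6 and
distance ≤ 8 Å a true contact.

Pairs involving unresolved residues are excluded from the labels *and*
from scoring denominators: a prediction that cannot be verified must not
count as a false positive.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import gemmi
import numpy as np
from scipy.spatial.distance import squareform, pdist

from .contact_io import CLASSES, ContactSet, TargetRecord, separation_class
from .errors import EmptyLabelError, InvalidInputError

logger = logging.getLogger(__name__)

__all__ = [
    "Residue",
    "StructureChain",
    "LabelSet",
    "representative_atom",
    "reconcile",
    "distance_matrix",
    "mean_distance_matrix",
    "contacts_from_distances",
    "read_structure_models",
    "build_labels",
    "labels_to_csv",
]


@dataclass(frozen=True)
class Residue:
    """One structure residue mapped onto the target sequence.

    ``position`` is the 1-based index into the target sequence;
    ``coord`` is the representative-atom coordinate in Å, or None when the
    residue has neither Cβ nor Cα resolved.
    """

    position: int
    amino_acid: str
    coord: np.ndarray | None


@dataclass
class StructureChain:
    """An ordered list of residues from one model of one chain."""

    target_id: str
    residues: list[Residue]

    def __post_init__(self) -> None:
        positions = [r.position for r in self.residues]
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise InvalidInputError(
                f"{self.target_id}: residue sequence positions must be strictly increasing"
            )


@dataclass
class LabelSet:
    """Ground truth for one target: distances, contacts and per-class counts."""

    target_id: str
    L: int
    distances: np.ndarray  # L×L, NaN where either residue is unresolved
    true_contacts: ContactSet
    n_true_per_class: dict[str, int]

    @property
    def resolved(self) -> np.ndarray:
        """Boolean L×L mask of pairs whose distance could be measured."""
        return np.isfinite(self.distances)


def representative_atom(
    atoms: Mapping[str, Sequence[float]], amino_acid: str
) -> np.ndarray | None:
    """Pick the residue's distance-defining atom coordinate.

    Cβ for all residues except glycine, which has none and uses Cα.  A
    non-glycine residue missing its Cβ falls back to Cα with a warning;
    when neither atom is present the residue is unresolved (returns None).
    """
    amino_acid = amino_acid.upper()
    if amino_acid != "G" and "CB" in atoms:
        return np.asarray(atoms["CB"], dtype=float)
    if "CA" in atoms:
        if amino_acid != "G" and "CB" not in atoms:
            warnings.warn(
                f"non-glycine residue ({amino_acid}) lacks CB; falling back to CA",
                stacklevel=2,
            )
        return np.asarray(atoms["CA"], dtype=float)
    return None


def reconcile(chain: StructureChain, target: TargetRecord) -> StructureChain:
    """Drop structure residues that disagree with the target sequence.

    Comparison is positional (no realignment): a residue at position k is
    kept iff its amino acid equals ``target.sequence[k-1]``.  Positions
    outside 1..L are also dropped.  Surviving residues keep their original
    positions.
    """
    kept = [
        r
        for r in chain.residues
        if 1 <= r.position <= target.L and r.amino_acid.upper() == target.sequence[r.position - 1]
    ]
    n_dropped = len(chain.residues) - len(kept)
    if n_dropped:
        logger.info(
            "%s: dropped %d/%d residues disagreeing with the target sequence",
            target.target_id,
            n_dropped,
            len(chain.residues),
        )
    if len(kept) < 2:
        raise EmptyLabelError(
            f"{target.target_id}: only {len(kept)} residues agree with the target sequence"
        )
    return StructureChain(target_id=target.target_id, residues=kept)


def distance_matrix(chain: StructureChain, L: int) -> np.ndarray:
    """L×L Euclidean distances between representative atoms, NaN when absent."""
    dist = np.full((L, L), np.nan)
    resolved = [(r.position - 1, r.coord) for r in chain.residues if r.coord is not None]
    if not resolved:
        return dist
    idx = np.array([k for k, _ in resolved])
    coords = np.array([c for _, c in resolved])
    sub = squareform(pdist(coords))
    dist[np.ix_(idx, idx)] = sub
    return dist


def mean_distance_matrix(models: Sequence[StructureChain], L: int) -> np.ndarray:
    """Per-pair mean distance over the models in which the pair is resolved.

    Used for NMR ensembles; a pair is unresolved only if it is unresolved
    in every model.
    """
    if not models:
        raise InvalidInputError("mean_distance_matrix needs at least one model")
    stack = np.stack([distance_matrix(m, L) for m in models])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)  # all-NaN slices
        return np.nanmean(stack, axis=0)


def contacts_from_distances(
    distances: np.ndarray,
    target_id: str,
    threshold: float = 8.0,
) -> tuple[ContactSet, dict[str, int]]:
    """All resolved pairs with separation ≥ 6 and distance ≤ threshold.

    The boundary is inclusive (a pair at exactly 8 Å is a contact).
    Returns the contact set and per-class counts — the n_true used as
    precision ceilings downstream.
    """
    distances = np.asarray(distances, dtype=float)
    L = distances.shape[0]
    iu, ju = np.triu_indices(L, k=6)
    d = distances[iu, ju]
    hit = np.isfinite(d) & (d <= threshold)
    pairs = {(int(i) + 1, int(j) + 1) for i, j in zip(iu[hit], ju[hit])}
    class_of = {p: separation_class(*p) for p in pairs}
    cset = ContactSet(target_id=target_id, pairs=frozenset(pairs), class_of_pair=class_of)
    counts = {cls: 0 for cls in CLASSES}
    for cls in class_of.values():
        counts[cls] += 1
    return cset, counts


# --- PDB reading ----------------------------------------------------------


def _one_letter(resname: str) -> str:
    info = gemmi.find_tabulated_residue(resname)
    if info is None or not info.is_amino_acid():
        return "X"
    return info.one_letter_code.upper()


def read_structure_models(
    path: str | Path,
    target_id: str | None = None,
    chain_id: str | None = None,
) -> list[StructureChain]:
    """Read a PDB (or mmCIF) file into one :class:`StructureChain` per MODEL.

    Only one chain is read — ``chain_id`` if given, else the first chain;
    other chains are skipped with a log line.  Residue ``seqid`` numbers are
    taken as 1-based positions in the target sequence (label structures are
    assumed pre-mapped to target numbering; reconcile drops any mismatch).
    """
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    if target_id is None:
        target_id = st.name or Path(path).stem
    models: list[StructureChain] = []
    for model in st:
        chains = list(model)
        if not chains:
            continue
        if chain_id is None:
            chain = chains[0]
        else:
            found = [c for c in chains if c.name == chain_id]
            if not found:
                raise InvalidInputError(f"{path}: no chain {chain_id!r} in model {model.name}")
            chain = found[0]
        if len(chains) > 1:
            logger.info(
                "%s model %s: reading chain %s, ignoring %d other chain(s)",
                path,
                model.name,
                chain.name,
                len(chains) - 1,
            )
        residues = []
        seen = set()
        for res in chain:
            pos = res.seqid.num
            if pos in seen:  # altloc / duplicate numbering: keep first
                continue
            seen.add(pos)
            atoms = {atom.name: (atom.pos.x, atom.pos.y, atom.pos.z) for atom in res}
            aa = _one_letter(res.name)
            residues.append(
                Residue(position=pos, amino_acid=aa, coord=representative_atom(atoms, aa))
            )
        residues.sort(key=lambda r: r.position)
        models.append(StructureChain(target_id=target_id, residues=residues))
    if not models:
        raise InvalidInputError(f"{path}: structure contains no models")
    return models


def build_labels(
    models: Sequence[StructureChain],
    target: TargetRecord,
    threshold: float = 8.0,
) -> LabelSet:
    """Reconcile each model against the target and derive the label set."""
    reconciled = [reconcile(m, target) for m in models]
    distances = mean_distance_matrix(reconciled, target.L)
    cset, counts = contacts_from_distances(distances, target.target_id, threshold)
    return LabelSet(
        target_id=target.target_id,
        L=target.L,
        distances=distances,
        true_contacts=cset,
        n_true_per_class=counts,
    )


def labels_to_csv(labels: LabelSet, path: str | Path) -> None:
    """Export labels as CSV rows (i, j, distance, class, is_contact) for
    every resolved pair with separation ≥ 6."""
    import csv

    iu, ju = np.triu_indices(labels.L, k=6)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["target_id", "i", "j", "distance", "class", "is_contact"])
        for i0, j0 in zip(iu, ju):
            d = labels.distances[i0, j0]
            if not np.isfinite(d):
                continue
            i, j = int(i0) + 1, int(j0) + 1
            writer.writerow(
                [
                    labels.target_id,
                    i,
                    j,
                    f"{d:.3f}",
                    separation_class(i, j),
                    int((i, j) in labels.true_contacts),
                ]
            )
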