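"""Distance-distribution (distogram) predictions and their conversion to
contact probabilities.

A distance-prediction network emits, for every residue pair (i, j), a
probability distribution over binned Cβ–Cβ distances.  The contact
probability at a threshold t (8 Å by convention) is the total probability
mass at distances ≤ t.  Because bin edges rarely coincide with the
threshold, the bin that straddles it contributes the fraction of its span
lying below t, under the model that mass is uniformly distributed within a
bin.  For a 64-bin scheme spanning 2–22 Å this yields full weight for bins
0–18 and 20% of bin 19 at the 8 Å threshold.

Distance below the smallest edge is physically impossible for real chains,
but any probability mass the network places there is counted as contact:
the "in contact" region starts at 0 Å, not at the first edge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .contact_io import ContactProbMap
from .errors import InvalidInputError, InvalidSchemeError

CONTACT_THRESHOLD = 8.0  # Å

__all__ = [
    "CONTACT_THRESHOLD",
    "BinScheme",
    "Distogram",
    "contact_weights",
    "integrate",
    "alphafold_like_scheme",
    "trrosetta_like_scheme",
    "prospr_like_scheme",
    "get_scheme",
    "SCHEME_PRESETS",
    "save_distogram",
    "load_distogram",
]


@dataclass(frozen=True)
class BinScheme:
    """Distance discretization used by one predictor.

    Parameters
    ----------
    edges
        Strictly increasing distance values in Å, length ``n_dist_bins + 1``.
        Distance bin ``k`` spans ``edges[k]``–``edges[k+1]``.
    has_no_contact_bin
        If True, total bin index 0 carries "farther than the last edge /
        not in contact" mass and the distance bins occupy total indices
        ``1 .. n_dist_bins``.
    name
        Free-text label used in logs and container files.
    """

    edges: np.ndarray
    has_no_contact_bin: bool = False
    name: str = ""

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges, dtype=float)
        object.__setattr__(self, "edges", edges)
        if edges.ndim != 1 or edges.size < 2:
            raise InvalidSchemeError(f"scheme {self.name!r}: need at least 2 edges")
        if not np.all(np.diff(edges) > 0):
            raise InvalidSchemeError(f"scheme {self.name!r}: edges must be strictly increasing")
        if edges[0] < 0:
            raise InvalidSchemeError(f"scheme {self.name!r}: edges must be non-negative")

    @property
    def n_dist_bins(self) -> int:
        return len(self.edges) - 1

    @property
    def n_total_bins(self) -> int:
        return self.n_dist_bins + (1 if self.has_no_contact_bin else 0)

    @property
    def dist_bin_offset(self) -> int:
        """Total-bin index of the first distance bin."""
        return 1 if self.has_no_contact_bin else 0


def alphafold_like_scheme() -> BinScheme:
    """64 equal-width distance bins spanning 2–22 Å, no no-contact bin."""
    return BinScheme(edges=np.linspace(2.0, 22.0, 65), name="alphafold-like")


def trrosetta_like_scheme() -> BinScheme:
    """Leading no-contact bin plus 36 distance bins of 0.5 Å starting at 2 Å."""
    return BinScheme(
        edges=np.arange(2.0, 20.0 + 0.25, 0.5),
        has_no_contact_bin=True,
        name="trrosetta-like",
    )


def prospr_like_scheme() -> BinScheme:
    """10 distance bins in which bins 0–2 jointly span 0–8 Å.

    The published description fixes the *inclusion set* (contact = bins 0–2
    of 10) but not the edges; this preset is a reconstruction chosen so that
    the three lowest bins cover 0–8 Å evenly and the remaining seven extend
    to 22 Å in 2 Å steps.
    """
    edges = np.concatenate([np.linspace(0.0, 8.0, 4), np.arange(10.0, 22.0 + 1.0, 2.0)])
    return BinScheme(edges=edges, name="prospr-like")


SCHEME_PRESETS = {
    "alphafold": alphafold_like_scheme,
    "trrosetta": trrosetta_like_scheme,
    "prospr": prospr_like_scheme,
}


def get_scheme(name: str) -> BinScheme:
    try:
        return SCHEME_PRESETS[name]()
    except KeyError:
        raise InvalidSchemeError(
            f"unknown scheme preset {name!r}; available: {sorted(SCHEME_PRESETS)}"
        ) from None


def contact_weights(scheme: BinScheme, threshold: float = CONTACT_THRESHOLD) -> np.ndarray:
    """Per-bin contribution of each total bin to the contact probability.

    Bins entirely below ``threshold`` weigh 1, the straddling bin weighs the
    fraction of its span below the threshold, bins above weigh 0, and the
    no-contact bin (when present) always weighs 0.  Mass below the first
    edge counts as contact, so the first distance bin is never penalized
    from below.
    """
    if threshold <= 0:
        raise InvalidInputError(f"threshold must be positive, got {threshold}")
    lo = scheme.edges[:-1]
    hi = scheme.edges[1:]
    w = np.clip((threshold - lo) / (hi - lo), 0.0, 1.0)
    if threshold <= scheme.edges[0]:
        warnings.warn(
            f"threshold {threshold} Å is at or below the smallest edge "
            f"{scheme.edges[0]} Å of scheme {scheme.name!r}; all weights are zero",
            stacklevel=2,
        )
    if scheme.has_no_contact_bin:
        w = np.concatenate([[0.0], w])
    return w


@dataclass
class Distogram:
    """Per-target distance-distribution prediction from one method.

    ``probs`` is an L×L×n_total_bins tensor; each pair's bin probabilities
    are non-negative and sum to 1 (tolerance 1e-6), and the tensor is
    symmetric in (i, j).  Slightly asymmetric tensors are symmetrized by
    averaging on validation, with a warning.
    """

    target_id: str
    probs: np.ndarray
    scheme: BinScheme
    sequence: str | None = None
    _validated: bool = field(default=False, repr=False, compare=False)

    @property
    def L(self) -> int:
        return self.probs.shape[0]

    def validate(self, atol: float = 1e-6) -> "Distogram":
        """Check invariants, symmetrizing near-symmetric tensors in place."""
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 3 or p.shape[0] != p.shape[1]:
            raise InvalidInputError(f"{self.target_id}: probs must be L×L×n_bins, got {p.shape}")
        if p.shape[2] != self.scheme.n_total_bins:
            raise InvalidInputError(
                f"{self.target_id}: {p.shape[2]} bins in tensor but scheme "
                f"{self.scheme.name!r} declares {self.scheme.n_total_bins}"
            )
        if p.min() < -atol:
            raise InvalidInputError(f"{self.target_id}: negative bin probability {p.min()}")
        sums = p.sum(axis=2)
        if not np.allclose(sums, 1.0, atol=atol):
            worst = np.abs(sums - 1.0).max()
            raise InvalidInputError(
                f"{self.target_id}: bin probabilities must sum to 1 (worst deviation {worst:.3g})"
            )
        pt = np.swapaxes(p, 0, 1)
        if not np.allclose(p, pt, atol=atol):
            raise InvalidInputError(f"{self.target_id}: probs not symmetric within {atol}")
        if not np.array_equal(p, pt):
            warnings.warn(
                f"{self.target_id}: distogram tensor not exactly symmetric; "
                "symmetrizing by averaging (i,j) and (j,i)",
                stacklevel=2,
            )
            p = 0.5 * (p + pt)
        self.probs = p
        self._validated = True
        return self


def integrate(
    distogram: Distogram, threshold: float = CONTACT_THRESHOLD
) -> ContactProbMap:
    """Sum each pair's bin probabilities up to ``threshold`` into a contact map.

    Each entry is the dot product of the pair's bin probabilities with
    :func:`contact_weights`; the output is symmetric with zero diagonal and
    entries in [0, 1].
    """
    if not distogram._validated:
        distogram.validate()
    w = contact_weights(distogram.scheme, threshold)
    p = distogram.probs @ w
    p = 0.5 * (p + p.T)
    np.clip(p, 0.0, 1.0, out=p)
    np.fill_diagonal(p, 0.0)
    return ContactProbMap(target_id=distogram.target_id, p=p, sequence=distogram.sequence)


def save_distogram(distogram: Distogram, path: str | Path) -> None:
    """Write a distogram container (NumPy ``.npz`` archive).

    The archive holds ``probs``, ``edges``, ``has_no_contact_bin``,
    ``scheme_name``, ``target_id`` and ``sequence``.
    """
    distogram.validate()
    np.savez_compressed(
        path,
        probs=distogram.probs,
        edges=distogram.scheme.edges,
        has_no_contact_bin=np.array(distogram.scheme.has_no_contact_bin),
        scheme_name=np.array(distogram.scheme.name),
        target_id=np.array(distogram.target_id),
        sequence=np.array(distogram.sequence or ""),
    )


def load_distogram(path: str | Path) -> Distogram:
    """Read a distogram container written by :func:`save_distogram`,
    validating invariants on load."""
    with np.load(path, allow_pickle=False) as data:
        try:
            scheme = BinScheme(
                edges=data["edges"],
                has_no_contact_bin=bool(data["has_no_contact_bin"]),
                name=str(data["scheme_name"]),
            )
            dg = Distogram(
                target_id=str(data["target_id"]),
                probs=np.asarray(data["probs"], dtype=float),
                scheme=scheme,
                sequence=str(data["sequence"]) or None,
            )
        except KeyError as exc:
            raise InvalidInputError(f"{path}: missing field {exc} in distogram container")
    return dg.validate()
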