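"""Synthetic targets and noisy predictors for end-to-end benchmarking.

Real benchmarks need archives of predictions plus solved structures; this
module replaces both with controllable stand-ins so that ensembling claims
can be tested from scratch:

* :func:`gen_chain` builds a compact self-avoiding random walk with a
  fixed 3.8 Å pseudo-bond (the Cα–Cα virtual bond length), excluded volume
  and protein-like packing density, so that short-, mid- and long-range
  contacts all occur.
* :func:`simulate_predictor` turns a target's true distance matrix into a
  distogram whose accuracy is set by a noise scale σ and whose errors can
  be correlated across predictors through a shared-error weight ρ — the
  knob that controls predictor diversity.  At ρ = 1 all predictors make
  identical errors and ensembling cannot help; at ρ = 0 their errors are
  independent and averaging cancels them.
* :func:`ensemble_experiment` runs families of such predictors and their
  mean-ensemble over many targets and scores everything, reproducing the
  qualitative finding that an ensemble of diverse, comparably accurate
  predictors beats each of its members.

All randomness flows from explicit integer seeds through a single
``SeedSequence`` hierarchy, so every run is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import gemmi
import numpy as np
from Bio.SeqUtils import seq3
from scipy.spatial.distance import pdist, squareform
from scipy.special import ndtr

from .contact_io import CLASSES, ContactProbMap, ContactSet, TargetRecord, top_L, write_rr
from .distogram import BinScheme, Distogram, integrate, trrosetta_like_scheme
from .ensembling import ensemble_mean
from .errors import InvalidInputError
from .labels import LabelSet, Residue, StructureChain, build_labels
from .scoring import EvaluationResult, aggregate, evaluate_map, jaccard_table

BOND_LENGTH = 3.8  # Å, consecutive-residue pseudo-bond
MIN_CLEARANCE = 3.5  # Å, excluded-volume radius for non-adjacent residues
RADIUS_FACTOR = 3.2  # Å, confinement radius = RADIUS_FACTOR * L^(1/3)
GLYCINE_FREQ = 0.07  # roughly the natural glycine frequency

_AA20 = "ACDEFGHIKLMNPQRSTVWY"

__all__ = [
    "SyntheticTarget",
    "PredictorSpec",
    "gen_chain",
    "simulate_predictor",
    "shared_noise_matrix",
    "ensemble_experiment",
    "ExperimentResult",
    "write_target_fixtures",
]


@dataclass
class SyntheticTarget:
    """A generated chain with its sequence, coordinates and derived labels."""

    target_id: str
    sequence: str
    coords: np.ndarray  # L×3, Å
    labels: LabelSet

    @property
    def L(self) -> int:
        return len(self.sequence)

    @property
    def record(self) -> TargetRecord:
        return TargetRecord(target_id=self.target_id, sequence=self.sequence)

    @property
    def distances(self) -> np.ndarray:
        return squareform(pdist(self.coords))


@dataclass(frozen=True)
class PredictorSpec:
    """One simulated predictor: noise scale, error correlation, bin scheme.

    ``sigma`` (Å) is both the scale of the predictor's distance error and
    the width of the Gaussian it spreads over the distance bins; ``rho``
    in [0, 1] is the weight of the error component shared with the other
    predictors of the family.
    """

    method_id: str
    sigma: float
    rho: float = 0.0
    scheme: BinScheme = field(default_factory=trrosetta_like_scheme)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise InvalidInputError(f"{self.method_id}: sigma must be >= 0")
        if not 0 <= self.rho <= 1:
            raise InvalidInputError(f"{self.method_id}: rho must be in [0, 1]")


def gen_chain(
    L: int,
    seed: int | np.random.SeedSequence,
    target_id: str | None = None,
    compaction_radius_factor: float = RADIUS_FACTOR,
    max_step_tries: int = 200,
    max_restarts: int = 100,
) -> SyntheticTarget:
    """Generate a compact self-avoiding chain and its ground-truth labels.

    The walk takes fixed 3.8 Å steps, rejects any placement closer than
    3.5 Å to a non-adjacent residue, and is confined to a sphere of radius
    ``compaction_radius_factor * L^(1/3)`` around the origin — the scaling
    of globular-protein packing density — so long-range contacts are
    guaranteed to form.  Placement dead-ends trigger a restart with a
    fresh sub-seed, up to ``max_restarts``.
    """
    if L < 15:
        raise InvalidInputError(f"gen_chain needs L >= 15, got {L}")
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    seq_ss, *walk_ss = root.spawn(1 + max_restarts)
    rng = np.random.default_rng(seq_ss)
    aa_probs = np.full(20, (1.0 - GLYCINE_FREQ) / 19)
    aa_probs[_AA20.index("G")] = GLYCINE_FREQ
    sequence = "".join(rng.choice(list(_AA20), size=L, p=aa_probs))
    radius = compaction_radius_factor * L ** (1.0 / 3.0)

    coords = None
    for attempt in range(max_restarts):
        coords = _attempt_walk(L, np.random.default_rng(walk_ss[attempt]), radius, max_step_tries)
        if coords is not None:
            break
    if coords is None:
        raise RuntimeError(f"chain generation failed after {max_restarts} restarts (L={L})")

    if target_id is None:
        target_id = f"SYN{L}_{root.entropy}"
    chain = StructureChain(
        target_id=target_id,
        residues=[
            Residue(position=k + 1, amino_acid=aa, coord=coords[k])
            for k, aa in enumerate(sequence)
        ],
    )
    record = TargetRecord(target_id=target_id, sequence=sequence)
    labels = build_labels([chain], record)
    return SyntheticTarget(target_id=target_id, sequence=sequence, coords=coords, labels=labels)


def _attempt_walk(
    L: int, rng: np.random.Generator, radius: float, max_step_tries: int
) -> np.ndarray | None:
    coords = np.empty((L, 3))
    coords[0] = 0.0
    for i in range(1, L):
        placed = False
        for _ in range(max_step_tries):
            step = rng.standard_normal(3)
            norm = np.linalg.norm(step)
            if norm == 0.0:
                continue
            cand = coords[i - 1] + BOND_LENGTH * step / norm
            if np.linalg.norm(cand) > radius:
                continue
            if i >= 2:
                d2 = np.sum((coords[: i - 1] - cand) ** 2, axis=1)
                if d2.min() < MIN_CLEARANCE**2:
                    continue
            coords[i] = cand
            placed = True
            break
        if not placed:
            return None
    return coords


def shared_noise_matrix(L: int, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Symmetric per-pair N(0, σ²) draw shared by all predictors of a family."""
    upper = np.triu(rng.standard_normal((L, L)), k=1)
    return sigma * (upper + upper.T)


def simulate_predictor(
    target: SyntheticTarget,
    spec: PredictorSpec,
    shared_noise: np.ndarray | None = None,
) -> Distogram:
    """Produce one predictor's distogram for a synthetic target.

    Each pair's perceived distance is
    ``d' = d + ρ·shared + sqrt(1−ρ²)·own`` with own-error ~ N(0, σ²), and
    the emitted distribution is a Gaussian of width σ centred on d',
    discretized over the predictor's bin scheme (tail mass beyond the last
    edge goes to the no-contact bin when the scheme has one, else to the
    last bin; mass below the first edge goes to the first distance bin).
    With σ = 0 the distogram is a delta in the bin containing the true
    distance.
    """
    L = target.L
    d = target.distances
    rng = np.random.default_rng(spec.seed)
    own = shared_noise_matrix(L, spec.sigma, rng)
    if shared_noise is None:
        shared_noise = np.zeros((L, L))
    dprime = d + spec.rho * shared_noise + np.sqrt(1.0 - spec.rho**2) * own

    scheme = spec.scheme
    edges = scheme.edges
    n_dist = scheme.n_dist_bins
    if spec.sigma == 0.0:
        idx = np.searchsorted(edges, dprime, side="right") - 1
        below = idx < 0
        beyond = idx >= n_dist
        idx = np.clip(idx, 0, n_dist - 1)
        dist_probs = np.zeros((L, L, n_dist))
        ii, jj = np.meshgrid(np.arange(L), np.arange(L), indexing="ij")
        dist_probs[ii, jj, idx] = 1.0
        dist_probs[below] = 0.0
        dist_probs[below, 0] = 1.0
        tail = beyond.astype(float)
        dist_probs[beyond] = 0.0
    else:
        cdf = ndtr((edges[None, None, :] - dprime[..., None]) / spec.sigma)
        dist_probs = np.diff(cdf, axis=2)
        dist_probs[..., 0] += cdf[..., 0]  # impossible sub-2 Å mass → first bin
        tail = 1.0 - cdf[..., -1]

    if scheme.has_no_contact_bin:
        probs = np.concatenate([tail[..., None], dist_probs], axis=2)
    else:
        probs = dist_probs
        probs[..., -1] += tail
    probs /= probs.sum(axis=2, keepdims=True)
    dg = Distogram(
        target_id=target.target_id, probs=probs, scheme=scheme, sequence=target.sequence
    )
    return dg.validate()


@dataclass
class ExperimentResult:
    """Outcome of one simulated ensembling experiment."""

    summary: "pd.DataFrame"  # rows: methods + 'ensemble'; cols: classes + overall
    jaccard: "pd.DataFrame"  # pairwise mean Jaccard distances between predictors
    per_method_results: dict[str, list[EvaluationResult]]
    params: dict

    def gain_over_best(self, cls: str = "long") -> float:
        """Ensemble accuracy minus the best individual accuracy in a class."""
        individual = self.summary.drop(index="ensemble")[cls]
        return float(self.summary.loc["ensemble", cls] - individual.max())


def ensemble_experiment(
    n_targets: int,
    L: int,
    k_predictors: int,
    sigma: float,
    rho: float,
    seed: int,
    scheme: BinScheme | None = None,
) -> ExperimentResult:
    """Score k noisy predictors and their mean-ensemble on generated targets.

    Targets and noise draws depend only on ``seed`` (not on ρ or σ), so
    sweeps over the error-correlation weight compare like with like.
    Returns per-class mean normalized accuracies per method and the mean
    pairwise Jaccard distances between the predictors' union-of-class
    top-L contact sets.
    """
    import pandas as pd

    if k_predictors < 2:
        raise InvalidInputError("ensemble_experiment needs k_predictors >= 2")
    if scheme is None:
        scheme = trrosetta_like_scheme()
    method_ids = [f"predictor_{k}" for k in range(k_predictors)]
    results: dict[str, list[EvaluationResult]] = {m: [] for m in method_ids + ["ensemble"]}
    union_sets: dict[str, dict[str, ContactSet]] = {m: {} for m in method_ids}

    root = np.random.SeedSequence(seed)
    for t, target_ss in enumerate(root.spawn(n_targets)):
        chain_ss, shared_ss, *pred_ss = target_ss.spawn(2 + k_predictors)
        target = gen_chain(L, chain_ss, target_id=f"SYN_{t:04d}")
        shared = shared_noise_matrix(L, sigma, np.random.default_rng(shared_ss))
        maps: list[ContactProbMap] = []
        for method_id, ss in zip(method_ids, pred_ss):
            spec = PredictorSpec(
                method_id=method_id,
                sigma=sigma,
                rho=rho,
                scheme=scheme,
                seed=int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF),
            )
            cmap = integrate(simulate_predictor(target, spec, shared))
            maps.append(cmap)
            results[method_id].append(evaluate_map(cmap, target.labels))
            union_sets[method_id][target.target_id] = _union_top_L(cmap, target.labels)
        ens = ensemble_mean(maps)
        results["ensemble"].append(evaluate_map(ens, target.labels))

    summary = pd.DataFrame({m: aggregate(r) for m, r in results.items()}).T
    jac = jaccard_table(union_sets)
    return ExperimentResult(
        summary=summary,
        jaccard=jac,
        per_method_results=results,
        params=dict(
            n_targets=n_targets, L=L, k_predictors=k_predictors, sigma=sigma, rho=rho, seed=seed
        ),
    )


def _union_top_L(cmap: ContactProbMap, labels: LabelSet) -> ContactSet:
    """Union of the per-class top-L selections (the object Jaccard compares)."""
    pairs: dict[tuple[int, int], str] = {}
    probs: dict[tuple[int, int], float] = {}
    for cls in CLASSES:
        sel = top_L(cmap, labels.L, cls, eligible=labels.resolved)
        for p in sel.pairs:
            pairs[p] = cls
            if p in sel.prob_of_pair:
                probs[p] = sel.prob_of_pair[p]
    return ContactSet(
        target_id=cmap.target_id,
        pairs=frozenset(pairs),
        class_of_pair=pairs,
        prob_of_pair=probs,
    )


# --- fixture emission -----------------------------------------------------


def write_target_fixtures(target: SyntheticTarget, outdir: str | Path) -> dict[str, Path]:
    """Write a synthetic target as FASTA + single-model PDB files.

    The PDB carries one representative atom per residue (CB, or CA for
    glycine), which is all the label pipeline reads.  Returns the paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta_path = outdir / f"{target.target_id}.fasta"
    with open(fasta_path, "w") as fh:
        fh.write(f">{target.target_id}\n")
        for k in range(0, target.L, 60):
            fh.write(target.sequence[k : k + 60] + "\n")

    st = gemmi.Structure()
    st.name = target.target_id
    model = gemmi.Model(1)
    chain = gemmi.Chain("A")
    for k, aa in enumerate(target.sequence):
        res = gemmi.Residue()
        res.name = seq3(aa).upper()
        res.seqid = gemmi.SeqId(k + 1, " ")
        atom = gemmi.Atom()
        atom.name = "CA" if aa == "G" else "CB"
        atom.element = gemmi.Element("C")
        atom.pos = gemmi.Position(*target.coords[k])
        atom.occ = 1.0
        res.add_atom(atom)
        chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    pdb_path = outdir / f"{target.target_id}.pdb"
    st.write_pdb(str(pdb_path))
    return {"fasta": fasta_path, "pdb": pdb_path}


def perfect_prediction(target: SyntheticTarget) -> ContactProbMap:
    """Noise-free contact map for a target (probability 1 on true contacts)."""
    spec = PredictorSpec(method_id="oracle", sigma=0.0, seed=0)
    return integrate(simulate_predictor(target, spec))
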