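# Methods

## Contacts from distance distributions

A distogram assigns each residue pair a probability vector over distance
bins defined by a strictly increasing edge list; optionally a leading
"no-contact" bin carries the mass beyond the last edge. The contact
probability at threshold t (default 8 Å) is the dot product of the bin
probabilities with a weight vector: 1 for bins entirely below t, 0 above,
and — under the model that **mass is uniformly distributed within a bin's
span** — the fraction (t − lower_edge)/width for the bin straddling t.
For the 64-bin preset spanning 2–22 Å this gives full weight to bins 0–18
and 20% to bin 19; for the preset with a no-contact bin and 0.5 Å bins
from 2 Å, bins 1–12 are fully included. Mass below the smallest edge is
physically impossible for real chains but is counted as contact
(conservative: the contact region starts at 0 Å). Near-symmetric input
tensors are symmetrized by averaging (i, j) and (j, i) with a warning,
since networks are near- but not exactly symmetric.

The 10-bin preset is a **reconstruction**: its published description fixes
only the inclusion set (contact = bins 0–2), so the shipped edges place
bins 0–2 evenly across 0–8 Å and seven 2 Å bins up to 22 Å. Only the
below-8 Å boundary matters for contact integration; the remaining edges
are a documented convention.

Distogram containers are NumPy `.npz` archives holding the probability
tensor, bin edges, the no-contact flag, scheme name, target id and
sequence; invariants (row sums 1 ± 1e−6, symmetry, non-negativity) are
validated on load.

## Separation classes, top-L selection, RR files

Pairs are classed by sequence separation s = |i−j|: short 6–11, mid
12–23, long ≥ 24; s < 6 is excluded from all evaluation. For each class
the L most probable pairs are declared in contact, where L is the length
of the sequence the predictors received (not the resolved-structure
length). Ties break deterministically: probability descending, then i,
then j ascending — the convention is arbitrary but makes outputs
bit-stable. Residue indices are 1-based at every API surface (the RR
convention) and converted once at array boundaries.

RR records are `i j d_low d_high probability`; a pair absent from a file
holds probability 0 rather than "missing", because submissions list only
confident pairs and the ensemble mean needs a defined value everywhere.

## Labels

The representative atom is Cβ, or Cα for glycine; a non-glycine residue
lacking Cβ falls back to Cα with a warning, and a residue with neither is
unresolved. Structures are reconciled against the target sequence
positionally — residues whose amino acid disagrees with the sequence at
their seqid position are dropped, without renumbering or realignment
(label structures are assumed pre-mapped to target numbering). For
multi-model (NMR) files the distance matrix is the per-pair mean over the
models in which the pair is resolved. A pair is a true contact iff both
residues are resolved, s ≥ 6 and distance ≤ 8 Å; the boundary is
inclusive, which at float precision on real coordinates is untestable but
fixes the contract. Pairs touching unresolved residues are removed
*before* top-L selection and excluded from precision denominators: a
prediction that cannot be verified must not count as a false positive.

## Scoring

With no negative predictions, accuracy reduces to precision TP/(TP+FP)
over the selected pairs. A target-class with n_true < L caps achievable
precision at n_true/L, so scores are normalized by the ceiling
min(1, n_true/L), equivalently score = TP/min(L, n_true). A class with
n_true = 0 is undefined and skipped in averages (scoring it 0 or 1 would
punish or reward a vacuous class). Aggregation is macro: per-class means
over targets first, then the mean of the class means; pooled
micro-averaging is available behind a flag for comparison. Jaccard
distance between two contact sets is (|A∪B| − |A∩B|)/|A∪B|, defined as 0
when both sets are empty; method-pair tables report per-class distances
plus their unweighted mean.

Sub-ensembles take the first ceil(fraction · n) of the ranked methods —
the only rounding under which the top 20% of 33 methods is 7. Ranking is
by overall accuracy descending, ties by method id.

## Synthetic generator

`gen_chain` emulates a folded chain as a self-avoiding random walk with
fixed 3.8 Å steps (the Cα–Cα virtual bond), a 3.5 Å excluded-volume
radius for non-adjacent residues, and confinement to a sphere of radius
3.2·L^(1/3) Å around the origin. The radius follows globular packing
density (~130 Å³ per residue); it makes short-, mid- and long-range
contacts all common (≈ 49/47/63 true contacts per class at L = 60 on
average), so every separation class is exercised. Sequences are random
over the 20 amino acids with glycine at 7% (its approximate natural
frequency); glycine only matters through the Cα rule in the label path.
Dead-ended walks restart with a fresh sub-seed (bounded retries).

`simulate_predictor` perceives each pair's distance as
`d' = d + ρ·shared + sqrt(1−ρ²)·own`, with own ~ N(0, σ²) private to the
predictor and `shared` a per-pair N(0, σ²) draw common to the family; it
emits a Gaussian of width σ centred on d', discretized over the bin
scheme (σ = 0 degenerates to a delta in the true bin). ρ is the
diversity dial: at ρ = 0 errors are independent and averaging cancels
them; at ρ = 1 all predictors are identical and ensembling cannot help.
This is the simplest mechanism that reproduces the qualitative claim that
dissimilar predictors of similar quality benefit most from ensembling.

What the generator does *not* emulate: real backbone geometry (no bond
angles, secondary structure, or side chains), systematic network biases
(alignment-depth dependence, overconfidence), or unresolved residues.
Passing tests therefore demonstrate the correctness of the pipeline and
the error-averaging mechanism, not the accuracy of any real predictor.

## Problem sizes and seeds

All randomness flows from explicit integer seeds through a single
`SeedSequence` hierarchy; targets and noise draws depend only on the seed,
not on σ or ρ, so correlation sweeps compare like with like. The shipped
experiment sizes — 100 targets of L = 100 with k = 3 predictors at
σ = 2 Å for the ensemble-gain result, 50 targets of L = 60 for the
noiseless identity — are large enough that the long-range gain (~0.12) is
far outside run-to-run variation; the gain result holds strictly under
every seed tried.

## Numerical choices

- Weight/integration tolerance: the analytic weights are exact; tests
  compare against an exact sub-bin overlap oracle at 1e−9.
- Distogram validation: row sums within 1e−6, symmetry within 1e−6.
- Probability maps are clipped to [0, 1] after integration; diagonals are
  zeroed.
- RR probabilities are printed with six decimals, records sorted by
  descending probability then (i, j) for byte-stable output.
- Degenerate inputs: empty member lists, zero models, all-undefined
  aggregates, thresholds at or below the first edge, and self-pairs all
  raise typed errors (or warn and return zeros where the contract says
  so) rather than propagating NaNs.

## Known limitations

- Reconciliation is positional; structures numbered differently from the
  target sequence must be renumbered upstream.
- No support for the extended "RR distance" format or multi-model RR
  files; one chain per structure file is read.
- The synthetic predictor's noise is additive Gaussian on distance;
  heavy-tailed or structured error families are out of scope.
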