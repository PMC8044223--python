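"""Label derivation: representative atoms, reconciliation, distances, contacts."""

import numpy as np
import pytest
from scipy.stats import ortho_group

from contactkit import (
    EmptyLabelError,
    InvalidInputError,
    StructureChain,
    TargetRecord,
    build_labels,
    contacts_from_distances,
    distance_matrix,
    mean_distance_matrix,
    read_structure_models,
    reconcile,
    representative_atom,
    write_target_fixtures,
)
from contactkit.labels import Residue


def chain_from_coords(coords, sequence, target_id="t"):
    return StructureChain(
        target_id=target_id,
        residues=[
            Residue(position=k + 1, amino_acid=aa, coord=np.asarray(c, dtype=float))
            for k, (aa, c) in enumerate(zip(sequence, coords))
        ],
    )


class TestRepresentativeAtom:
    def test_glycine_uses_ca(self):
        assert representative_atom({"CA": (0, 0, 0)}, "G").tolist() == [0, 0, 0]

    def test_non_glycine_prefers_cb(self):
        coord = representative_atom({"CA": (0, 0, 0), "CB": (1, 2, 3)}, "A")
        assert coord.tolist() == [1, 2, 3]

    def test_missing_cb_falls_back_to_ca_with_warning(self):
        with pytest.warns(UserWarning, match="lacks CB"):
            coord = representative_atom({"CA": (4, 5, 6)}, "A")
        assert coord.tolist() == [4, 5, 6]

    def test_no_backbone_atoms_is_absent(self):
        assert representative_atom({"N": (0, 0, 0)}, "A") is None


class TestReconcile:
    def test_mismatching_position_dropped_neighbours_kept(self):
        target = TargetRecord(target_id="t", sequence="AKRA")
        chain = chain_from_coords(np.zeros((4, 3)), "AKKA")
        out = reconcile(chain, target)
        assert [r.position for r in out.residues] == [1, 2, 4]

    def test_perfect_agreement_is_identity(self, rng):
        target = TargetRecord(target_id="t", sequence="ACDEFGHIKL")
        chain = chain_from_coords(rng.normal(size=(10, 3)), target.sequence)
        out = reconcile(chain, target)
        assert [r.position for r in out.residues] == list(range(1, 11))

    def test_decoy_mismatches_removed_per_position(self, rng):
        """Exactly the positions where a shuffled decoy disagrees are removed."""
        target = TargetRecord(target_id="t", sequence="ACDEFGHIKLMNPQRSTVWY")
        decoy = list(target.sequence)
        flipped = rng.choice(20, size=10, replace=False)
        for k in flipped:
            decoy[k] = "W" if decoy[k] != "W" else "Y"
        chain = chain_from_coords(rng.normal(size=(20, 3)), "".join(decoy))
        expected = [k + 1 for k in range(20) if k not in flipped]
        out = reconcile(chain, target)
        assert [r.position for r in out.residues] == expected

    def test_fewer_than_two_survivors_is_an_error(self):
        target = TargetRecord(target_id="t", sequence="AAAA")
        chain = chain_from_coords(np.zeros((4, 3)), "KKKA")
        with pytest.raises(EmptyLabelError):
            reconcile(chain, target)


class TestDistanceMatrix:
    def test_three_four_five_triangle(self):
        chain = chain_from_coords([(0, 0, 0), (3, 4, 0)], "AA")
        d = distance_matrix(chain, 2)
        assert d[0, 1] == pytest.approx(5.0)
        assert d[0, 0] == 0.0

    def test_absent_coordinate_makes_pair_unresolved(self):
        chain = StructureChain(
            target_id="t",
            residues=[
                Residue(1, "A", np.zeros(3)),
                Residue(2, "A", None),
                Residue(3, "A", np.ones(3)),
            ],
        )
        d = distance_matrix(chain, 3)
        assert np.isnan(d[0, 1]) and np.isnan(d[1, 2])
        assert np.isfinite(d[0, 2])

    def test_matches_double_loop_oracle(self, rng):
        coords = rng.normal(scale=10, size=(12, 3))
        chain = chain_from_coords(coords, "A" * 12)
        d = distance_matrix(chain, 12)
        for i in range(12):
            for j in range(12):
                expected = np.sqrt(((coords[i] - coords[j]) ** 2).sum())
                assert d[i, j] == pytest.approx(expected, abs=1e-12)


class TestMeanDistanceMatrix:
    def test_boundary_contact_via_mean(self):
        """A pair at 7 and 9 Å across two models averages to 8 Å: a contact."""
        seq = "A" * 10
        coords1 = np.zeros((10, 3))
        coords2 = np.zeros((10, 3))
        for k in range(10):
            coords1[k] = coords2[k] = (100.0 * k, 0.0, 0.0)
        coords1[9] = (coords1[0][0] + 7.0, 0, 0)
        coords2[9] = (coords2[0][0] + 9.0, 0, 0)
        m1 = chain_from_coords(coords1, seq)
        m2 = chain_from_coords(coords2, seq)
        mean = mean_distance_matrix([m1, m2], 10)
        assert mean[0, 9] == pytest.approx(8.0)
        cset, _ = contacts_from_distances(mean, "t")
        assert (1, 10) in cset

    def test_single_model_equals_distance_matrix(self, rng):
        chain = chain_from_coords(rng.normal(scale=8, size=(8, 3)), "A" * 8)
        np.testing.assert_allclose(
            mean_distance_matrix([chain], 8), distance_matrix(chain, 8)
        )

    def test_copies_of_one_model_equal_single(self, rng):
        chain = chain_from_coords(rng.normal(scale=8, size=(8, 3)), "A" * 8)
        np.testing.assert_allclose(
            mean_distance_matrix([chain] * 4, 8), distance_matrix(chain, 8)
        )

    def test_pair_resolved_in_any_model_is_resolved(self):
        a = StructureChain("t", [Residue(1, "A", np.zeros(3)), Residue(2, "A", None)])
        b = StructureChain("t", [Residue(1, "A", np.zeros(3)), Residue(2, "A", np.ones(3))])
        mean = mean_distance_matrix([a, b], 2)
        assert np.isfinite(mean[0, 1])  # taken from the one model that has it

    def test_matches_explicit_average_oracle(self, rng):
        models = [chain_from_coords(rng.normal(scale=8, size=(7, 3)), "A" * 7) for _ in range(5)]
        mean = mean_distance_matrix(models, 7)
        stack = [distance_matrix(m, 7) for m in models]
        for i in range(7):
            for j in range(7):
                assert mean[i, j] == pytest.approx(
                    np.mean([s[i, j] for s in stack]), abs=1e-12
                )

    def test_zero_models_rejected(self):
        with pytest.raises(InvalidInputError):
            mean_distance_matrix([], 5)


class TestContactsFromDistances:
    def test_exact_threshold_is_a_contact(self):
        d = np.full((10, 10), 50.0)
        np.fill_diagonal(d, 0.0)
        d[0, 7] = d[7, 0] = 8.0
        cset, counts = contacts_from_distances(d, "t")
        assert (1, 8) in cset
        assert counts == {"short": 1, "mid": 0, "long": 0}

    def test_small_separation_excluded_even_when_close(self):
        d = np.full((10, 10), 50.0)
        d[0, 4] = d[4, 0] = 3.0  # separation 4
        cset, _ = contacts_from_distances(d, "t")
        assert len(cset) == 0

    def test_counts_sum_to_total(self, small_target):
        counts = small_target.labels.n_true_per_class
        assert sum(counts.values()) == len(small_target.labels.true_contacts)

    def test_helix_like_chain_matches_enumeration(self):
        """Toy regular helix: contacts agree with explicit enumeration."""
        t = np.arange(30)
        coords = np.c_[2.3 * np.cos(t * 1.75), 2.3 * np.sin(t * 1.75), 1.5 * t]
        d = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
        cset, _ = contacts_from_distances(d, "t")
        expected = {
            (i + 1, j + 1)
            for i in range(30)
            for j in range(i + 6, 30)
            if d[i, j] <= 8.0
        }
        assert cset.pairs == expected


def test_labels_invariant_under_rigid_motion(rng, small_target):
    """Rotating + translating the coordinates leaves the labels unchanged."""
    record = small_target.record
    base = chain_from_coords(small_target.coords, small_target.sequence)
    ref = build_labels([base], record)
    for _ in range(3):
        rot = ortho_group.rvs(3, random_state=rng)
        moved = chain_from_coords(
            small_target.coords @ rot.T + rng.normal(scale=50, size=3),
            small_target.sequence,
        )
        labels = build_labels([moved], record)
        assert labels.true_contacts.pairs == ref.true_contacts.pairs
        np.testing.assert_allclose(labels.distances, ref.distances, atol=1e-8)


def test_pdb_round_trip_reproduces_labels(tmp_path, small_target):
    """Labels rebuilt from an emitted PDB file equal the in-memory labels."""
    paths = write_target_fixtures(small_target, tmp_path)
    models = read_structure_models(paths["pdb"], target_id=small_target.target_id)
    assert len(models) == 1
    labels = build_labels(models, small_target.record)
    np.testing.assert_allclose(labels.distances, small_target.labels.distances, atol=5e-3)
    # PDB coordinates are quantized to 0.001 Å, so the contact call may flip
    # only for pairs essentially on the 8 Å boundary
    for i, j in labels.true_contacts.pairs ^ small_target.labels.true_contacts.pairs:
        assert abs(small_target.labels.distances[i - 1, j - 1] - 8.0) < 5e-3
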