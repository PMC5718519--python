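"""Calpha pairing and Kabsch superposition with outlier rejection."""

import copy

import numpy as np
import pytest

from oracles import quaternion_rmsd
from polprofiler import fixtures as fx
from polprofiler.domain_model import load_domain_map
from polprofiler.superpose import (FitError, PairingError, domain_rmsd,
                                   kabsch_fit, pair_calpha,
                                   refine_superposition)


@pytest.fixture(scope="module")
def helix():
    open_s, _, _ = fx.make_rotation_pair(0.0, n_residues=60)
    return open_s


def _transformed(s, rotation, translation):
    out = copy.deepcopy(s)
    out.id = s.id + "_t"
    for res in out.residues:
        for atom in res.atoms:
            atom.coords = rotation @ atom.coords + translation
    return out


class TestPairing:
    def test_self_pairing_is_total_with_identity_one(self, helix):
        pairs = pair_calpha(helix, helix)
        assert len(pairs) == 60
        assert pairs.identity == pytest.approx(1.0)

    def test_deleted_residues_reduce_pair_count(self, helix):
        other = copy.deepcopy(helix)
        other.id = "short"
        del other.residues[20:25]
        assert len(pair_calpha(helix, other)) == 55

    def test_no_protein_chain_raises(self, helix):
        dna, _ = fx.make_duplex_complex()
        with pytest.raises(PairingError):
            pair_calpha(helix, dna)

    def test_index_mode(self, helix):
        pairs = pair_calpha(helix, helix, mode="index")
        assert len(pairs) == 60 and pairs.provenance == "index"


class TestKabsch:
    def test_identical_coordinates_give_zero_rmsd_identity_rotation(
            self, helix):
        fit = kabsch_fit(pair_calpha(helix, helix))
        assert fit.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(fit.rotation, np.eye(3), atol=1e-9)
        assert abs(np.linalg.det(fit.rotation) - 1.0) < 1e-9

    def test_known_rigid_transform_recovered(self, helix):
        rot = fx._rotation_matrix(np.array([0.2, -1.0, 0.5]), 71.0)
        moved = _transformed(helix, rot, np.array([3.0, -1.0, 8.0]))
        fit = kabsch_fit(pair_calpha(helix, moved))
        assert np.allclose(fit.rotation, rot, atol=1e-9)
        assert fit.rmsd == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(6))
    def test_small_point_sets_match_quaternion_oracle(self, seed):
        """Kabsch RMSD equals the quaternion eigenvalue solution to 1e-6
        on <=8-point sets."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        xa = rng.normal(scale=5.0, size=(n, 3))
        xb = rng.normal(scale=5.0, size=(n, 3))
        from polprofiler.superpose import _kabsch
        _, _, rmsd = _kabsch(xa, xb)
        assert rmsd == pytest.approx(quaternion_rmsd(xa, xb), abs=1e-6)

    def test_two_printed_four_point_sets_match_oracle(self):
        xa = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
        xb = np.array([[0.1, 0, 0], [1, 0.2, 0], [0, 1.1, 0],
                       [-0.1, 0, 0.9]])
        from polprofiler.superpose import _kabsch
        _, _, rmsd = _kabsch(xa, xb)
        assert rmsd == pytest.approx(quaternion_rmsd(xa, xb), abs=1e-6)

    def test_too_few_or_collinear_points_raise(self, helix):
        pairs = pair_calpha(helix, helix)
        with pytest.raises(FitError):
            kabsch_fit(pairs.subset(np.arange(len(pairs)) < 2))
        from polprofiler.superpose import _kabsch
        line = np.outer(np.arange(5.0), np.array([1.0, 0, 0]))
        with pytest.raises(FitError):
            _kabsch(line, line)

    def test_rmsd_invariant_under_rigid_transform_of_either_input(
            self, helix):
        rng = np.random.default_rng(3)
        other = copy.deepcopy(helix)
        other.id = "noisy"
        for res in other.residues:
            for atom in res.atoms:
                atom.coords = atom.coords + rng.normal(0, 0.5, 3)
        base = kabsch_fit(pair_calpha(helix, other)).rmsd
        rot = fx._rotation_matrix(np.array([1.0, 2.0, -1.0]), 33.0)
        moved = _transformed(other, rot, np.array([-4.0, 2.0, 1.0]))
        assert kabsch_fit(pair_calpha(helix, moved)).rmsd == \
            pytest.approx(base, abs=1e-9)


class TestRefinement:
    def test_planted_outlier_rejected_rmsd_returns_to_zero(self, helix):
        other = copy.deepcopy(helix)
        other.id = "outlier"
        other.residues[10].atoms[0].coords = \
            other.residues[10].atoms[0].coords + np.array([10.0, 0.0, 0.0])
        fit = refine_superposition(pair_calpha(helix, other))
        assert fit.n_pairs_final == fit.n_pairs_initial - 1
        assert fit.rmsd == pytest.approx(0.0, abs=1e-9)
        assert fit.rejected[0][0].seq_id == 11

    def test_no_outliers_keeps_all_pairs(self, helix):
        fit = refine_superposition(pair_calpha(helix, helix))
        assert fit.n_pairs_final == fit.n_pairs_initial
        assert fit.cycles_run <= 5

    def test_rmsd_non_increasing_over_cycles(self, helix):
        rng = np.random.default_rng(11)
        other = copy.deepcopy(helix)
        other.id = "jittered"
        for res in other.residues:
            for atom in res.atoms:
                atom.coords = atom.coords + rng.normal(0, 0.8, 3)
        pairs = pair_calpha(helix, other)
        rmsds = [refine_superposition(pairs, cycles=c).rmsd
                 for c in range(1, 6)]
        assert all(b <= a + 1e-12 for a, b in zip(rmsds, rmsds[1:]))


def test_domain_rmsd_restricts_to_domain(helix):
    dmap = load_domain_map({"domains": {
        "helix": {"core": [["A", 1, 30]]},
        "perturbed": {"core": [["A", 1, 30]]}}})
    other = copy.deepcopy(helix)
    other.id = "perturbed"
    # displace residues outside the domain; domain fit must not see them
    for res in other.residues:
        if res.seq_id > 30:
            for atom in res.atoms:
                atom.coords = atom.coords + np.array([25.0, 0.0, 0.0])
    fit = domain_rmsd(helix, other, dmap, "core")
    assert fit.n_pairs_initial == 30
    assert fit.rmsd == pytest.approx(0.0, abs=1e-9)
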