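import numpy as np
import pytest

from h1ub import cg_model
from h1ub.cg_model import (
    CoarseGrainedSystem,
    ForwardModel,
    NuisanceParameters,
    RepresentationConfig,
    build_representation,
    crosslink_loglik,
    prior_score,
    system_from_truth,
    total_score,
)
from h1ub.ms_filters import WeightedCrossLink
from h1ub.seqchem import ResidueRangeSet


def naive_total_score(system, links, nuisance=NuisanceParameters(), forward=ForwardModel()):
    """Independent brute-force re-evaluation of the Bayesian score."""
    xyz = system.coords
    loglik = 0.0
    for link in links:
        i = system.bead_for_residue(link.protein_a, link.residue_a)
        j = system.bead_for_residue(link.protein_b, link.residue_b)
        d = float(np.sqrt(sum((xyz[i][k] - xyz[j][k]) ** 2 for k in range(3))))
        psi = nuisance.psi[min(link.ld_class, len(nuisance.psi) - 1)]
        f = 1.0 / (1.0 + np.exp((d - forward.d0) / forward.lam))
        loglik += link.weight * np.log(psi + (1 - psi) * f)
    conn = 0.0
    for i, j, span in system.topology:
        cap = system.radii[i] + system.radii[j] + 4.0 * np.sqrt(span)
        d = float(np.linalg.norm(xyz[i] - xyz[j]))
        conn += max(d - cap, 0.0) ** 2
    ev = 0.0
    bonded = {(min(i, j), max(i, j)) for i, j, _ in system.topology}
    same_body = set()
    for body in system.rigid_bodies:
        for a in body:
            for b in body:
                if a < b:
                    same_body.add((int(a), int(b)))
    n = system.n_beads
    for a in range(n):
        for b in range(a + 1, n):
            if (a, b) in bonded or (a, b) in same_body:
                continue
            d = float(np.linalg.norm(xyz[a] - xyz[b]))
            overlap = system.radii[a] + system.radii[b] - d
            if overlap > 0:
                ev += overlap**2
    return -loglik + conn + ev


class TestBuildRepresentation:
    @pytest.mark.parametrize("start,end,expected", [(120, 221, 6), (27, 44, 1)])
    def test_flexible_bead_counts(self, start, end, expected):
        config = RepresentationConfig(
            flexible_regions={"H1": ResidueRangeSet([(start, end)])}
        )
        system = build_representation(config, structures={})
        assert system.n_beads == expected

    def test_rigid_only(self):
        structures = {"U": {i: np.array([float(i), 0, 0]) for i in range(1, 6)}}
        system = build_representation(RepresentationConfig(), structures=structures)
        assert system.n_beads == 5
        assert (system.radii == 2.3).all()
        assert len(system.rigid_bodies) == 1

    def test_fixed_flag(self):
        structures = {"R": {1: np.zeros(3), 2: np.array([4.0, 0, 0])}}
        config = RepresentationConfig(fixed_proteins=("R",))
        system = build_representation(config, structures=structures)
        assert system.fixed_bodies == [True]

    def test_conjugation_edge_added(self):
        structures = {
            "Ub": {i: np.array([float(i) * 4, 0, 0]) for i in range(1, 77)},
            "H1": {i: np.array([0, float(i) * 4, 0]) for i in range(60, 70)},
        }
        config = RepresentationConfig(conjugation_edges=(("Ub", 76, "H1", 64),))
        system = build_representation(config, structures=structures)
        i = system.bead_for_residue("Ub", 76)
        j = system.bead_for_residue("H1", 64)
        assert any({a, b} == {i, j} for a, b, _ in system.topology)

    def test_overlapping_flexible_region_rejected(self):
        structures = {"H1": {i: np.array([float(i), 0, 0]) for i in range(1, 30)}}
        config = RepresentationConfig(
            flexible_regions={"H1": ResidueRangeSet([(25, 44)])}
        )
        with pytest.raises(ValueError):
            build_representation(config, structures=structures)

    def test_pdb_reading(self, tmp_path):
        # minimal two-residue PDB with a second MODEL that must be ignored
        pdb = tmp_path / "toy.pdb"
        pdb.write_text(
            "MODEL        1\n"
            "ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N\n"
            "ATOM      2  CA  ALA A   1       1.000   2.000   3.000  1.00  0.00           C\n"
            "ATOM      3  CA  GLY A   2       4.000   5.000   6.000  1.00  0.00           C\n"
            "ENDMDL\n"
            "MODEL        2\n"
            "ATOM      1  CA  ALA A   1       9.000   9.000   9.000  1.00  0.00           C\n"
            "ENDMDL\n"
            "END\n"
        )
        config = RepresentationConfig(rigid_sources={"X": [(str(pdb), "A", (1, 2))]})
        system = build_representation(config)
        np.testing.assert_allclose(
            system.coords, [[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]]
        )

    def test_missing_residues_raise_build_error(self, tmp_path):
        pdb = tmp_path / "toy.pdb"
        pdb.write_text(
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\nEND\n"
        )
        config = RepresentationConfig(rigid_sources={"X": [(str(pdb), "A", (50, 60))]})
        with pytest.raises(ValueError, match="absent"):
            build_representation(config)


class TestCrosslinkLoglik:
    def test_zero_links_is_zero(self, five_bead_system):
        system, _ = five_bead_system
        assert crosslink_loglik(system, []) == 0.0

    def test_monotone_in_distance(self, five_bead_system):
        system, _ = five_bead_system
        link = [WeightedCrossLink("A", 1, "B", 1, 1, 35.0, 2)]
        near = system.coords.copy()
        near[2] = near[0] + [5.0, 0, 0]
        far = system.coords.copy()
        far[2] = far[0] + [50.0, 0, 0]
        nuis = NuisanceParameters(psi=(0.05, 0.05, 0.05))
        assert crosslink_loglik(system, link, nuis, coords=near) > crosslink_loglik(
            system, link, nuis, coords=far
        )

    def test_weight_three_scales_contribution(self, five_bead_system):
        system, _ = five_bead_system
        w1 = [WeightedCrossLink("A", 1, "B", 1, 1, 35.0, 1)]
        w3 = [WeightedCrossLink("A", 1, "B", 1, 3, 35.0, 1)]
        assert crosslink_loglik(system, w3) == pytest.approx(
            3 * crosslink_loglik(system, w1), rel=1e-12
        )

    def test_unmapped_residue_names_link(self, five_bead_system):
        system, _ = five_bead_system
        bad = [WeightedCrossLink("A", 99, "B", 1, 1, 35.0, 1)]
        with pytest.raises(KeyError, match="99"):
            crosslink_loglik(system, bad)


class TestPriors:
    def test_satisfied_chain_scores_zero(self):
        coords = np.array([[0.0, 0, 0], [5.0, 0, 0], [10.0, 0, 0]])
        system = CoarseGrainedSystem(
            coords=coords,
            radii=np.full(3, 2.3),
            proteins=np.array(["A"] * 3, dtype=object),
            res_start=np.array([1, 2, 3]),
            res_end=np.array([1, 2, 3]),
            rigid_bodies=[],
            fixed_bodies=[],
            topology=[(0, 1, 1), (1, 2, 1)],
        )
        conn, ev = prior_score(system)
        assert conn == 0.0 and ev == 0.0

    def test_overlap_penalized(self):
        coords = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        system = CoarseGrainedSystem(
            coords=coords,
            radii=np.full(2, 3.0),
            proteins=np.array(["A", "B"], dtype=object),
            res_start=np.array([1, 1]),
            res_end=np.array([1, 1]),
            rigid_bodies=[],
            fixed_bodies=[],
            topology=[],
        )
        conn, ev = prior_score(system)
        assert ev > 0

    def test_connectivity_quadratic_in_gap(self):
        def stretched(d):
            coords = np.array([[0.0, 0, 0], [d, 0, 0]])
            return CoarseGrainedSystem(
                coords=coords,
                radii=np.full(2, 2.3),
                proteins=np.array(["A", "A"], dtype=object),
                res_start=np.array([1, 2]),
                res_end=np.array([1, 2]),
                rigid_bodies=[],
                fixed_bodies=[],
                topology=[(0, 1, 1)],
            )

        cap = 2.3 + 2.3 + 4.0
        c1, _ = prior_score(stretched(cap + 2.0))
        c2, _ = prior_score(stretched(cap + 4.0))
        assert c2 == pytest.approx(4 * c1, rel=1e-9)


class TestTotalScore:
    def test_no_links_satisfied_priors_zero(self):
        coords = np.array([[0.0, 0, 0], [10.0, 0, 0]])
        system = CoarseGrainedSystem(
            coords=coords,
            radii=np.full(2, 2.3),
            proteins=np.array(["A", "B"], dtype=object),
            res_start=np.array([1, 1]),
            res_end=np.array([1, 1]),
            rigid_bodies=[],
            fixed_bodies=[],
            topology=[],
        )
        assert total_score(system, []).total == 0.0

    def test_decreases_as_violated_link_shrinks(self, five_bead_system):
        system, _ = five_bead_system
        link = [WeightedCrossLink("A", 1, "B", 2, 1, 35.0, 2)]
        far = system.coords.copy()
        far[2:4] += [30.0, 0, 0]
        nearer = system.coords.copy()
        nearer[2:4] += [10.0, 0, 0]
        assert (
            total_score(system, link, coords=nearer).total
            < total_score(system, link, coords=far).total
        )

    def test_matches_naive_reimplementation(self, five_bead_system):
        system, links = five_bead_system
        got = total_score(system, links)
        assert got.total == pytest.approx(naive_total_score(system, links), abs=1e-9)
        assert got.total == pytest.approx(
            -got.crosslink_loglik + got.connectivity + got.excluded_volume, abs=1e-12
        )

    def test_invariant_under_global_rigid_motion(self, five_bead_system):
        system, links = five_bead_system
        theta = 0.7
        rot = np.array(
            [[np.cos(theta), -np.sin(theta), 0], [np.sin(theta), np.cos(theta), 0], [0, 0, 1]]
        )
        moved = system.coords @ rot.T + np.array([13.0, -4.0, 2.5])
        assert total_score(system, links, coords=moved).total == pytest.approx(
            total_score(system, links).total, abs=1e-9
        )

    def test_1d_scan_minimum_matches_grid_oracle(self):
        # two 1-bead bodies, one crosslink: scan the separation distance
        def system_at(d):
            return CoarseGrainedSystem(
                coords=np.array([[0.0, 0, 0], [d, 0, 0]]),
                radii=np.full(2, 2.3),
                proteins=np.array(["A", "B"], dtype=object),
                res_start=np.array([1, 1]),
                res_end=np.array([1, 1]),
                rigid_bodies=[],
                fixed_bodies=[],
                topology=[],
            )

        link = [WeightedCrossLink("A", 1, "B", 1, 1, 35.0, 2)]
        grid = np.arange(1.0, 50.0, 0.05)
        scores = [total_score(system_at(d), link).total for d in grid]
        best = grid[int(np.argmin(scores))]
        # analytic: mixture is monotone decreasing in d below d0, so the
        # minimum sits at the excluded-volume contact distance
        nuis = NuisanceParameters()
        fm = ForwardModel()
        analytic = [
            -1 * np.log(nuis.psi[2] + (1 - nuis.psi[2]) * fm(d)) + max(4.6 - d, 0) ** 2
            for d in grid
        ]
        assert best == pytest.approx(grid[int(np.argmin(analytic))], abs=1e-9)


class TestSystemFromTruth:
    def test_rigid_distances_preserved_after_randomize(self, small_truth):
        rng = np.random.default_rng(0)
        system = system_from_truth(small_truth, fixed=("body0",), randomize=rng)
        idx = system.protein_beads("body1")
        got = np.linalg.norm(
            system.coords[idx][:, None] - system.coords[idx][None], axis=-1
        )
        ref = np.linalg.norm(
            small_truth.bodies["body1"][:, None] - small_truth.bodies["body1"][None],
            axis=-1,
        )
        np.testing.assert_allclose(got, ref, atol=1e-6)

    def test_fixed_body_stays_at_truth(self, small_truth):
        rng = np.random.default_rng(0)
        system = system_from_truth(small_truth, fixed=("body0",), randomize=rng)
        idx = system.protein_beads("body0")
        np.testing.assert_array_equal(system.coords[idx], small_truth.bodies["body0"])
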