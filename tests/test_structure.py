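"""Geometric feature computations against brute-force and analytic oracles."""

import numpy as np
import pytest
from scipy.spatial import ConvexHull

from stratvep.structure import (
    active_site_distance,
    assign_secondary_structure,
    build_profile,
    compute_buriedness,
    count_contacts,
    derive_contact_radius,
    read_structure,
    write_structure,
)
from tests.conftest import chain_structure


def brute_force_hull_distance(point: np.ndarray, cloud: np.ndarray) -> float:
    """Min distance from the point to any hull facet plane (independent path:
    explicit facet enumeration instead of a vectorized matrix product)."""
    hull = ConvexHull(cloud)
    best = np.inf
    for eq in hull.equations:
        normal, offset = eq[:3], eq[3]
        best = min(best, abs(normal @ point + offset) / np.linalg.norm(normal))
    return best


class TestBuriedness:
    def test_hull_vertex_is_zero(self, cube_structure):
        assert compute_buriedness(cube_structure, 1) == pytest.approx(0.0, abs=1e-12)

    def test_cube_center_is_half(self, cube_structure):
        # analytic: the center of a unit cube is 0.5 from every face
        assert compute_buriedness(cube_structure, 9) == pytest.approx(0.5, abs=1e-12)

    def test_matches_brute_force_on_random_cloud(self, random_cloud):
        cloud = random_cloud.heavy_atoms()
        for pos in (3, 17, 42):
            expected = brute_force_hull_distance(
                random_cloud.residues[pos - 1].ca, cloud
            )
            assert compute_buriedness(random_cloud, pos) == pytest.approx(expected, abs=1e-9)

    def test_rigid_transform_invariance(self, random_cloud):
        rng = np.random.default_rng(7)
        # random rotation (QR of a Gaussian matrix) + translation
        Q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        t = rng.uniform(-50, 50, 3)
        moved = chain_structure(random_cloud.ca_coords @ Q.T + t)
        for pos in (1, 10, 30):
            assert compute_buriedness(moved, pos) == pytest.approx(
                compute_buriedness(random_cloud, pos), abs=1e-8
            )

    def test_degenerate_cloud_raises(self):
        flat = chain_structure(np.c_[np.arange(5.0), np.arange(5.0) * 2, np.zeros(5)])
        with pytest.raises(ValueError):
            compute_buriedness(flat, 1)


class TestContactRadius:
    def test_zero_variance_spacing(self):
        coords = np.c_[np.arange(10.0) * 3.8, np.zeros(10), np.zeros(10)]
        assert derive_contact_radius(chain_structure(coords)) == pytest.approx(3.8)

    def test_alternating_spacings_hand_arithmetic(self):
        # consecutive distances alternate 3.0, 5.0 -> mean 4.0, sample SD ~1.03
        xs = np.cumsum([0.0, 3.0, 5.0, 3.0, 5.0])
        coords = np.c_[xs, np.zeros(5), np.zeros(5)]
        d = np.array([3.0, 5.0, 3.0, 5.0])
        expected = d.mean() + 2 * d.std(ddof=1)
        assert derive_contact_radius(chain_structure(coords)) == pytest.approx(expected)

    def test_needs_three_residues(self):
        with pytest.raises(ValueError):
            derive_contact_radius(chain_structure(np.zeros((2, 3)) + [[0, 0, 0], [3.8, 0, 0]]))


class TestContacts:
    def test_direct_count(self):
        coords = np.array([[0, 0, 0], [5, 0, 0], [10, 0, 0]], dtype=float)
        model = chain_structure(coords)
        assert count_contacts(model, 1, radius=7.3) == 1

    def test_isolated_residue(self):
        coords = np.array([[0, 0, 0], [100, 0, 0], [200, 0, 0]], dtype=float)
        assert count_contacts(chain_structure(coords), 1, radius=7.3) == 0

    def test_matches_pairwise_oracle_and_symmetry(self, random_cloud):
        coords = random_cloud.ca_coords
        radius = 8.0
        d = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
        for i in range(len(coords)):
            expected = int(((d[i] <= radius) & (np.arange(len(coords)) != i)).sum())
            assert count_contacts(random_cloud, i + 1, radius) == expected
        # symmetry: j within radius of i iff i within radius of j
        within = (d <= radius) & ~np.eye(len(coords), dtype=bool)
        assert (within == within.T).all()


class TestActiveSiteDistance:
    def test_self_distance_zero(self, random_cloud):
        assert active_site_distance(random_cloud, 5, [5, 20]) == pytest.approx(0.0)

    def test_minimum_of_sites(self):
        coords = np.array([[0, 0, 0], [8.5, 0, 0], [0, 12, 0]], dtype=float)
        model = chain_structure(coords)
        assert active_site_distance(model, 1, [2, 3]) == pytest.approx(8.5)

    def test_missing_site_raises(self, random_cloud):
        with pytest.raises(KeyError):
            active_site_distance(random_cloud, 1, [999])
        with pytest.raises(ValueError):
            active_site_distance(random_cloud, 1, [])


class TestSecondaryStructure:
    def test_interval_membership(self):
        coords = np.c_[np.arange(30.0) * 3.8, np.zeros(30), np.zeros(30)]
        model = chain_structure(coords, ss_records=[("helix", 10, 20)])
        labels = assign_secondary_structure(model)
        assert labels.loc[10] == 1 and labels.loc[20] == 1
        assert labels.loc[9] == 0 and labels.loc[21] == 0

    def test_no_records_all_negative(self, random_cloud):
        assert (assign_secondary_structure(random_cloud) == 0).all()

    def test_override_precedence(self):
        coords = np.c_[np.arange(10.0) * 3.8, np.zeros(10), np.zeros(10)]
        model = chain_structure(coords, ss_records=[("sheet", 2, 4)])
        labels = assign_secondary_structure(model, override={3: 0, 8: 1})
        assert labels.loc[3] == 0 and labels.loc[8] == 1
        with pytest.raises(ValueError):
            assign_secondary_structure(model, override={99: 1})


class TestProfile:
    def test_completeness_and_composition(self, random_cloud):
        profile = build_profile(random_cloud, active_sites=[5, 20])
        assert len(profile) == 50
        assert set(profile.table.columns) == {"aa", "buriedness", "n_contacts", "active_site_distance", "ss"}
        # composition oracle: profile entries equal individually computed operations
        radius = derive_contact_radius(random_cloud)
        assert profile.contact_radius == pytest.approx(radius)
        for pos in (1, 13, 50):
            row = profile.table.loc[pos]
            assert row["buriedness"] == pytest.approx(compute_buriedness(random_cloud, pos))
            assert row["n_contacts"] == count_contacts(random_cloud, pos, radius)
            assert row["active_site_distance"] == pytest.approx(
                active_site_distance(random_cloud, pos, [5, 20])
            )

    def test_deterministic(self, random_cloud):
        a = build_profile(random_cloud, [5, 20])
        b = build_profile(random_cloud, [5, 20])
        assert a.table.equals(b.table) and a.contact_radius == b.contact_radius

    def test_csv_roundtrip(self, random_cloud, tmp_path):
        from stratvep.structure import StructuralProfile

        profile = build_profile(random_cloud, [5, 20])
        profile.to_csv(tmp_path / "p.csv")
        back = StructuralProfile.from_csv(tmp_path / "p.csv")
        assert back.contact_radius == pytest.approx(profile.contact_radius)
        assert back.active_sites == (5, 20)
        assert np.allclose(back.table["buriedness"], profile.table["buriedness"])


class TestPdbIO:
    def test_roundtrip_preserves_positions_and_records(self, tmp_path):
        rng = np.random.default_rng(0)
        coords = rng.uniform(0, 30, (25, 3))
        model = chain_structure(coords, ss_records=[("helix", 3, 9), ("sheet", 15, 20)],
                                aas="ACDEFGHIKLMNPQRSTVWYACDEF")
        path = tmp_path / "toy.pdb"
        write_structure(model, path)
        back = read_structure(path)
        assert list(back.positions) == list(model.positions)
        assert back.sequence == model.sequence
        assert np.allclose(back.ca_coords, model.ca_coords, atol=1e-3)  # PDB has 3 decimals
        assert sorted(back.ss_records) == sorted(model.ss_records)

    def test_missing_file_and_chain(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_structure(tmp_path / "nope.pdb")
        coords = np.c_[np.arange(5.0) * 3.8, np.zeros(5), np.zeros(5)]
        path = tmp_path / "a.pdb"
        write_structure(chain_structure(coords), path)
        with pytest.raises(ValueError):
            read_structure(path, chain="Z")

    def test_offset_mapping(self, tmp_path):
        coords = np.c_[np.arange(5.0) * 3.8, np.zeros(5), np.zeros(5)]
        path = tmp_path / "a.pdb"
        write_structure(chain_structure(coords), path)
        shifted = read_structure(path, offset=30)
        assert list(shifted.positions) == [31, 32, 33, 34, 35]
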