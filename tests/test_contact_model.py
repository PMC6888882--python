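import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from memcoev import (ContactMap, InvalidInputError, SiteClasses,
                     contact_map_from_coordinates, contact_map_from_pdb, submap,
                     synthetic_contact_map)
from memcoev.contact_model import (read_contact_map, read_site_classes,
                                   write_contact_map, write_site_classes)


class TestContactMapType:
    def test_rejects_asymmetric(self):
        m = np.zeros((3, 3), dtype=bool)
        m[0, 1] = True
        with pytest.raises(InvalidInputError):
            ContactMap(m)

    def test_rejects_self_contact(self):
        m = np.eye(3, dtype=bool)
        with pytest.raises(InvalidInputError):
            ContactMap(m)

    def test_from_edges_roundtrip(self):
        cmap = ContactMap.from_edges(5, [(0, 2), (3, 4)])
        assert cmap.edges() == [(0, 2), (3, 4)]
        assert cmap.contact(2, 0) == 1 and cmap.contact(0, 3) == 0


class TestFromCoordinates:
    @pytest.mark.parametrize("distance,expected", [(9.0, 1), (12.0, 0), (10.0, 0)])
    def test_threshold_is_strict(self, distance, expected):
        coords = [(0.0, 0.0, 0.0), (distance, 0.0, 0.0)]
        cmap = contact_map_from_coordinates(coords, threshold=10.0)
        assert cmap.contact(0, 1) == expected

    def test_collinear_points(self):
        coords = [(0, 0, 0), (6, 0, 0), (12, 0, 0)]
        cmap = contact_map_from_coordinates(coords, threshold=10.0)
        assert cmap.edges() == [(0, 1), (1, 2)]

    @pytest.mark.parametrize("bad", [[], [(0.0, 0.0, np.nan)]])
    def test_invalid_coordinates(self, bad):
        with pytest.raises(InvalidInputError):
            contact_map_from_coordinates(bad)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_rigid_motion_invariance(self, seed):
        rng = np.random.default_rng(seed)
        coords = rng.uniform(0, 30, size=(12, 3))
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        moved = coords @ q.T + rng.uniform(-50, 50, size=3)
        assert contact_map_from_coordinates(coords) == contact_map_from_coordinates(moved)


class TestSyntheticMap:
    def test_pure_band(self):
        cmap, classes = synthetic_contact_map(20, (), 0.0, backbone_width=2, seed=1)
        ii, kk = np.meshgrid(np.arange(20), np.arange(20), indexing="ij")
        expected = (np.abs(ii - kk) >= 1) & (np.abs(ii - kk) <= 2)
        assert np.array_equal(cmap.matrix, expected)
        assert not classes.structured.any()

    def test_helix_span_adds_periodicity_contacts(self):
        cmap, classes = synthetic_contact_map(20, [(5, 15)], 0.0, backbone_width=2, seed=1)
        band, _ = synthetic_contact_map(20, (), 0.0, backbone_width=2, seed=1)
        extra = cmap.matrix & ~band.matrix
        ii, kk = np.nonzero(np.triu(extra))
        for i, k in zip(ii, kk):
            assert k - i in (3, 4)
            assert 5 <= i and k < 15
        # every offset-3/4 pair inside the span is present
        for i in range(5, 15):
            for off in (3, 4):
                if i + off < 15:
                    assert cmap.contact(i, i + off) == 1
        assert np.array_equal(classes.structured, (np.arange(20) >= 5) & (np.arange(20) < 15))

    def test_overlapping_spans_rejected(self):
        with pytest.raises(InvalidInputError):
            synthetic_contact_map(30, [(0, 10), (5, 15)], 0.0, 2, seed=0)

    def test_minimum_length(self):
        with pytest.raises(InvalidInputError):
            synthetic_contact_map(5, (), 0.0, 2, seed=0)

    def test_long_range_mean_per_site(self):
        """Monte-Carlo: mean long-range contacts per site matches the request."""
        lam, L = 1.0, 200
        means = []
        for seed in range(50):
            cmap, _ = synthetic_contact_map(L, (), lam, backbone_width=2, seed=seed)
            band, _ = synthetic_contact_map(L, (), 0.0, backbone_width=2, seed=seed)
            extra = cmap.matrix & ~band.matrix
            means.append(extra.sum() / L)
        mu, se = np.mean(means), np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(mu - lam) < 3 * se

    def test_deterministic_given_seed(self):
        a, _ = synthetic_contact_map(50, [(10, 20)], 2.0, 2, seed=123)
        b, _ = synthetic_contact_map(50, [(10, 20)], 2.0, 2, seed=123)
        assert a == b


class TestSubmap:
    def test_band_translation_invariance(self, band_map):
        sub, mapping = submap(band_map, 5, 10)
        ref, _ = synthetic_contact_map(10, (), 0.0, backbone_width=2, seed=0)
        assert sub == ref
        assert np.array_equal(mapping, np.arange(5, 15))

    def test_identity_window(self, band_map):
        sub, _ = submap(band_map, 0, band_map.L)
        assert sub == band_map

    def test_restriction_matches_parent(self):
        cmap, _ = synthetic_contact_map(30, (), 3.0, 2, seed=7)
        sub, mapping = submap(cmap, 3, 5)
        for a in range(5):
            for b in range(5):
                assert sub.matrix[a, b] == cmap.matrix[mapping[a], mapping[b]]

    @given(st.integers(0, 10), st.integers(2, 10), st.integers(0, 5), st.integers(1, 5))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_composition(self, a, n, b, m):
        cmap, _ = synthetic_contact_map(25, (), 2.0, 2, seed=3)
        if a + n > cmap.L or b + m > n:
            return
        outer, _ = submap(cmap, a, n)
        nested, _ = submap(outer, b, m)
        direct, _ = submap(cmap, a + b, m)
        assert nested == direct

    def test_out_of_range(self, band_map):
        with pytest.raises(InvalidInputError):
            submap(band_map, 15, 10)


class TestSerialization:
    def test_map_roundtrip(self, tmp_path):
        cmap, classes = synthetic_contact_map(40, [(5, 20)], 2.0, 2, seed=9)
        write_contact_map(cmap, tmp_path / "m.txt")
        assert read_contact_map(tmp_path / "m.txt") == cmap
        write_site_classes(classes, tmp_path / "c.txt")
        back = read_site_classes(tmp_path / "c.txt")
        assert np.array_equal(back.structured, classes.structured)

    def test_bad_class_codes(self):
        with pytest.raises(InvalidInputError):
            SiteClasses.from_codes(["S", "X"])


PDB_LINES = """\
ATOM      1  N   ALA A   1      -1.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      3  CA  GLY A   2       6.000   0.000   0.000  1.00  0.00           C
ATOM      4  CA  SER A   3      12.000   0.000   0.000  1.00  0.00           C
TER
END
"""


def test_pdb_reader(tmp_path):
    """Synthetic 3-residue chain: contacts follow Cα geometry, N atoms ignored."""
    pdb = tmp_path / "toy.pdb"
    pdb.write_text(PDB_LINES)
    cmap = contact_map_from_pdb(pdb, threshold=10.0)
    assert cmap.L == 3
    assert cmap.edges() == [(0, 1), (1, 2)]
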