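"""Bouton-field classification, separation projection, exclusion zone."""

import numpy as np
import pytest
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

import islandcircuit as ic
from islandcircuit import fields

from conftest import SMALL_GENERATOR


def _two_balls(rng, n_a=600, n_b=1200, r_a=8000.0, r_b=12000.0, sep=40000.0):
    """Dense compact ball (island analogue) + larger ball, well separated."""
    def ball(n, r, center):
        d = rng.normal(size=(n, 3))
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        u = rng.random(n) ** (1 / 3)
        return center + r * d * u[:, None]
    A = ball(n_a, r_a, np.zeros(3))
    B = ball(n_b, r_b, np.array([sep, 0.0, 0.0]))
    return A, B


class TestClassifyBoutons:
    def test_two_separated_balls_fully_recovered(self):
        rng = np.random.default_rng(0)
        A, B = _two_balls(rng)
        P = np.vstack([A, B])
        lab = fields.classify_boutons(P)
        counts = lab.counts
        assert counts["ambiguous"] == 0
        truth = np.array(["island"] * len(A) + ["nonisland"] * len(B), dtype=object)
        assert np.mean(lab.labels == truth) >= 0.99  # denser ball is the island

    def test_single_ball_sets_no_split_flag(self):
        rng = np.random.default_rng(1)
        A, _ = _two_balls(rng)
        lab = fields.classify_boutons(A)
        assert lab.no_split
        assert set(lab.labels) <= {"island", "ambiguous"}

    def test_conservation_of_labels(self, small_labeling):
        lab, pos = small_labeling
        counts = lab.counts
        assert counts["island"] + counts["nonisland"] + counts["ambiguous"] == len(pos)

    def test_mid_shell_boutons_are_exactly_the_ambiguous_ones(self):
        """Boutons dropped into the middle of the exclusion zone (the TC17
        geometry) are ambiguous; every field bouton keeps its field."""
        cfg = ic.GeneratorConfig(seed=0, exclusion_width=15000.0)
        ds, truth = ic.generate(cfg)
        ids, pos = ds.rgc_bouton_positions()
        c = np.array(truth.island_center)
        r = np.array(truth.island_radii)
        rng = np.random.default_rng(100)
        extra = []
        for _ in range(3):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            extra.append(c + (r + truth.exclusion_width / 2) * u)
        P = np.vstack([pos, extra])
        all_ids = ids + ["mid0", "mid1", "mid2"]
        lab = fields.classify_boutons(P, ids=all_ids, level_fraction=0.05)
        amb = {sid for sid, lb in zip(all_ids, lab.labels) if lb == "ambiguous"}
        assert amb == {"mid0", "mid1", "mid2"}

    def test_fewer_than_two_boutons_rejected(self):
        with pytest.raises(ValueError):
            fields.classify_boutons(np.zeros((1, 3)))

    def test_labeling_json_round_trip(self, small_labeling, tmp_path):
        lab, pos = small_labeling
        p = lab.to_json(tmp_path / "lab.json")
        back = fields.BoutonFieldLabeling.from_json(p)
        assert list(back.labels) == list(lab.labels)
        np.testing.assert_array_equal(back.component_grid, lab.component_grid)
        np.testing.assert_allclose(back.frame.rotation, lab.frame.rotation)
        regions_a = lab.point_region(pos[:50])
        regions_b = back.point_region(pos[:50])
        assert list(regions_a) == list(regions_b)


class TestSeparationProjection:
    @staticmethod
    def _slab_clouds(seed, g=8000.0):
        rng = np.random.default_rng(seed)
        A = rng.random((1500, 3)) * [20000, 30000, 30000]
        B = rng.random((1500, 3)) * [20000, 30000, 30000] + [20000 + g, 0, 0]
        R = Rotation.random(random_state=seed + 50).as_matrix()
        P = np.vstack([A, B]) @ R.T + [55555.0, -220.0, 9999.0]
        normal = R @ np.array([1.0, 0.0, 0.0])
        return P, normal, g

    @pytest.mark.parametrize("seed", [3, 9])
    def test_slab_gap_recovered(self, seed):
        P, normal, g = self._slab_clouds(seed)
        lab = fields.classify_boutons(P, bandwidth=2000.0)
        proj = fields.find_separation_projection(lab, P, angular_resolution=3.0)
        assert abs(proj.margin - g) <= 0.05 * g
        angle = np.degrees(np.arccos(min(1.0, abs(np.dot(proj.axis, normal)))))
        assert angle <= 3.0
        # oracle: the margin can never exceed the closest inter-class pair
        isl = lab.labels == "island"
        non = lab.labels == "nonisland"
        d_min = cKDTree(P[isl]).query(P[non])[0].min()
        assert proj.margin <= d_min + 1e-6

    def test_rotation_is_orthonormal(self):
        P, _, _ = self._slab_clouds(3)
        lab = fields.classify_boutons(P, bandwidth=2000.0)
        proj = fields.find_separation_projection(lab, P, angular_resolution=5.0)
        R = proj.rotation
        np.testing.assert_allclose(R @ R.T, np.eye(3), atol=1e-9)
        assert abs(np.linalg.det(R) - 1.0) < 1e-9

    def test_interpenetrating_clouds_report_overlap(self):
        rng = np.random.default_rng(4)
        C = rng.normal(0, 6000, (800, 3))
        D = rng.normal(0, 6000, (800, 3)) + [30000, 0, 0]
        P = np.vstack([C, D])
        lab = fields.classify_boutons(P, bandwidth=2500.0)
        proj = fields.find_separation_projection(lab, P, angular_resolution=4.0)
        assert proj.margin == 0.0
        assert proj.overlap_count > 0

    def test_empty_class_is_precondition_error(self):
        rng = np.random.default_rng(5)
        A, _ = _two_balls(rng)
        lab = fields.classify_boutons(A)
        with pytest.raises(ValueError, match="non-empty"):
            fields.find_separation_projection(lab, A)


class TestExclusionZone:
    def test_generator_width_recovered(self, small_labeling):
        lab, pos = small_labeling
        w = SMALL_GENERATOR["exclusion_width"]
        gap = fields.measure_exclusion_zone(lab, pos)
        assert 0.8 * w <= gap.median_nm <= 1.3 * w
        assert not gap.no_zone

    def test_touching_fields_flagged_no_zone(self):
        """Collapsing the gap between labeled fields yields a median 'gap'
        on the inter-bouton-spacing scale, flagged below the no-zone line."""
        rng = np.random.default_rng(6)
        A = rng.random((2500, 3)) * [20000, 30000, 30000]
        B = rng.random((2500, 3)) * [20000, 30000, 30000] + [28000, 0, 0]
        P = np.vstack([A, B])
        lab = fields.classify_boutons(P, bandwidth=2000.0)
        assert not lab.no_split
        # translate the non-island slab so the supports just interdigitate
        shifted = P.copy()
        shifted[lab.labels == "nonisland"] -= [9000.0, 0.0, 0.0]
        gap = fields.measure_exclusion_zone(lab, shifted)
        assert gap.no_zone
        assert gap.median_nm < lab.bandwidth

    def test_density_doubling_leaves_gap_stable(self):
        meds = []
        for scale in (1, 2):
            cfg = dict(SMALL_GENERATOR)
            cfg["island_bouton_count"] *= scale
            cfg["nonisland_bouton_count"] *= scale
            ds, _ = ic.generate(ic.GeneratorConfig(seed=13, **cfg))
            ids, pos = ds.rgc_bouton_positions()
            lab = ic.classify_boutons(pos, ids=ids)
            meds.append(fields.measure_exclusion_zone(lab, pos).median_nm)
        assert abs(meds[1] - meds[0]) / meds[0] <= 0.10


class TestRigidMotionEquivariance:
    def test_labels_margin_and_gap_invariant(self, small_labeling):
        lab, pos = small_labeling
        M = Rotation.random(random_state=21).as_matrix()
        shift = np.array([1.2e6, -4.4e5, 8.8e5])
        pos_t = pos @ M.T + shift
        lab_t = ic.classify_boutons(pos_t, ids=lab.bouton_ids)
        assert list(lab_t.labels) == list(lab.labels)
        g0 = fields.measure_exclusion_zone(lab, pos)
        g1 = fields.measure_exclusion_zone(lab_t, pos_t)
        np.testing.assert_allclose(g1.median_nm, g0.median_nm, rtol=1e-6)
        p0 = fields.find_separation_projection(lab, pos, angular_resolution=6.0)
        p1 = fields.find_separation_projection(lab_t, pos_t, angular_resolution=6.0)
        np.testing.assert_allclose(p1.margin, p0.margin, rtol=1e-6, atol=1e-6)
        assert p1.overlap_count == p0.overlap_count
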