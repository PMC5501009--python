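"""Measure projection: truncated-Gaussian densities, ROI weights, mixing.

The brute-force oracles re-implement the projection as explicit loops
over dipoles and voxels, independent of the vectorized code paths.
"""

import numpy as np
import pytest

from frproi.headmodel import standard_head
from frproi.projection import (ROIAtlas, dipole_density, normalize_total_variance,
                               project_at, roi_measure, roi_weights, toy_atlas)

SIGMA = 12.0
T = 3.0


def _naive_density(locs, vox, sigma=SIGMA, t=T):
    P = np.zeros((len(locs), len(vox)))
    for i, x in enumerate(locs):
        for j, y in enumerate(vox):
            d = np.linalg.norm(np.asarray(y) - np.asarray(x))
            if d <= t * sigma:
                P[i, j] = (2 * np.pi * sigma**2) ** -1.5 * np.exp(
                    -0.5 * d**2 / sigma**2)
    return P


class TestDensity:
    def test_closed_form_center_and_truncation(self):
        locs = np.array([[0.0, 0.0, 0.0]])
        vox = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 35.9], [0.0, 0.0, 36.1]])
        d = dipole_density(locs, vox, sigma=SIGMA, truncation=T)
        assert d.P[0, 0] == pytest.approx((2 * np.pi * SIGMA**2) ** -1.5)
        assert d.P[0, 1] > 0.0
        assert d.P[0, 2] == 0.0
        assert np.argmax(d.P[0]) == 0

    def test_matches_bruteforce_oracle(self, rng):
        locs = rng.uniform(-50, 50, size=(7, 3))
        vox = rng.uniform(-60, 60, size=(40, 3))
        d = dipole_density(locs, vox)
        assert np.allclose(d.P, _naive_density(locs, vox), rtol=1e-12)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            dipole_density(np.zeros((1, 3)), np.zeros((1, 3)), sigma=0.0)


class TestProjectAt:
    def test_single_ic_returns_its_measure(self, rng):
        vox = np.array([[0.0, 0.0, 5.0]])
        d = dipole_density(np.array([[0.0, 0.0, 0.0]]), vox)
        M = rng.standard_normal((1, 4, 6))
        assert np.allclose(project_at(M, d, 0), M[0])

    def test_equidistant_ics_average(self, rng):
        vox = np.array([[0.0, 0.0, 0.0]])
        locs = np.array([[10.0, 0.0, 0.0], [-10.0, 0.0, 0.0]])
        d = dipole_density(locs, vox)
        M = rng.standard_normal((2, 5))
        assert np.allclose(project_at(M, d, 0), M.mean(axis=0))

    def test_zero_density_voxel_rejected(self):
        vox = np.array([[100.0, 100.0, 100.0]])
        d = dipole_density(np.array([[0.0, 0.0, 0.0]]), vox)
        with pytest.raises(ValueError):
            project_at(np.ones((1, 2)), d, 0)

    def test_random_case_matches_naive_loop(self, rng):
        locs = rng.uniform(-30, 30, size=(5, 3))
        vox = rng.uniform(-20, 20, size=(15, 3))
        d = dipole_density(locs, vox)
        M = rng.standard_normal((5, 8))
        P = _naive_density(locs, vox)
        for j in range(len(vox)):
            expect = sum(P[i, j] * M[i] for i in range(5)) / P[:, j].sum()
            assert np.allclose(project_at(M, d, j), expect, rtol=1e-10)


class TestROIWeights:
    def _atlas(self):
        return ROIAtlas(rois={
            "left": np.array([[-20.0, 0.0, 0.0], [-25.0, 0.0, 0.0]]),
            "right": np.array([[20.0, 0.0, 0.0], [25.0, 0.0, 0.0]]),
        }, spacing_mm=5.0)

    def test_single_dipole_one_hot(self):
        atlas = self._atlas()
        vox, _ = atlas.stacked()
        d = dipole_density(np.array([[-22.0, 0.0, 0.0]]), vox)
        w = roi_weights(d, atlas)
        assert w.w[0, 0] == pytest.approx(1.0)
        # the right ROI is beyond t*sigma = 36 mm, so it carries no mass
        assert w.empty_rois == ("right",)
        assert np.all(w.w >= 0)

    def test_mirror_symmetry_half_half(self):
        atlas = self._atlas()
        vox, _ = atlas.stacked()
        locs = np.array([[-22.0, 0.0, 0.0], [22.0, 0.0, 0.0]])
        d = dipole_density(locs, vox)
        w = roi_weights(d, atlas)
        assert w.w[0, 0] == pytest.approx(w.w[1, 1])
        assert np.allclose(w.w.sum(axis=0), 1.0, atol=1e-10)

    def test_matches_voxel_sum_oracle(self, rng):
        atlas = ROIAtlas(rois={
            "a": rng.uniform(-30, 0, size=(12, 3)),
            "b": rng.uniform(0, 30, size=(9, 3)),
        }, spacing_mm=8.0)
        vox, slices = atlas.stacked()
        locs = rng.uniform(-25, 25, size=(6, 3))
        d = dipole_density(locs, vox)
        w = roi_weights(d, atlas)
        P = _naive_density(locs, vox)
        for j, name in enumerate(atlas.names):
            mass_i = P[:, slices[name]].sum(axis=1)
            assert np.allclose(w.w[:, j], mass_i / mass_i.sum(), rtol=1e-10)

    def test_weight_conservation_everywhere(self, rng):
        """Columns sum to one at every voxel and ROI carrying mass."""
        head = standard_head()
        atlas = toy_atlas(head)
        vox, _ = atlas.stacked()
        locs = head.center + rng.uniform(-40, 40, size=(10, 3))
        d = dipole_density(locs, vox)
        mass = d.P.sum(axis=0)
        w_vox = d.P[:, mass > 0] / mass[mass > 0]
        assert np.allclose(w_vox.sum(axis=0), 1.0, atol=1e-10)
        w = roi_weights(d, atlas)
        live = [j for j, n in enumerate(atlas.names) if n not in w.empty_rois]
        assert np.allclose(w.w[:, live].sum(axis=0), 1.0, atol=1e-10)

    def test_locality_distant_dipole_has_no_influence(self):
        atlas = self._atlas()
        vox, _ = atlas.stacked()
        near = np.array([[-22.0, 0.0, 0.0]])
        far = np.array([[-22.0, 0.0, 200.0]])   # > t*sigma from every voxel
        w1 = roi_weights(dipole_density(near, vox), atlas)
        w2 = roi_weights(dipole_density(np.vstack([near, far]), vox), atlas)
        assert np.allclose(w2.w[0], w1.w[0])
        assert np.allclose(w2.w[1], 0.0)


class TestROIMeasure:
    def test_one_hot_and_uniform_weights(self, rng):
        atlas = ROIAtlas(rois={"r": np.array([[0.0, 0.0, 0.0]])},
                         spacing_mm=8.0)
        vox, _ = atlas.stacked()
        M = rng.standard_normal((3, 4, 7))
        d1 = dipole_density(np.array([[0.0, 0.0, 0.0],
                                      [200.0, 0.0, 0.0],
                                      [210.0, 0.0, 0.0]]), vox)
        w1 = roi_weights(d1, atlas)
        assert np.allclose(roi_measure(M, w1, "r"), M[0])
        locs = np.array([[8.0, 0.0, 0.0], [-8.0, 0.0, 0.0],
                         [0.0, 8.0, 0.0]])
        w2 = roi_weights(dipole_density(locs, vox), atlas)
        assert np.allclose(roi_measure(M, w2, "r"), M.mean(axis=0))

    def test_linearity_in_measures(self, rng):
        atlas = ROIAtlas(rois={"r": rng.uniform(-10, 10, size=(5, 3))},
                         spacing_mm=8.0)
        vox, _ = atlas.stacked()
        w = roi_weights(dipole_density(rng.uniform(-15, 15, (4, 3)), vox),
                        atlas)
        A = rng.standard_normal((4, 6))
        B = rng.standard_normal((4, 6))
        assert np.allclose(roi_measure(2 * A + 3 * B, w, "r"),
                           2 * roi_measure(A, w, "r") +
                           3 * roi_measure(B, w, "r"))

    def test_empty_roi_rejected(self):
        atlas = ROIAtlas(rois={"void": np.array([[500.0, 0.0, 0.0]])},
                         spacing_mm=8.0)
        vox, _ = atlas.stacked()
        w = roi_weights(dipole_density(np.zeros((1, 3)), vox), atlas)
        assert w.empty_rois == ("void",)
        with pytest.raises(ValueError):
            roi_measure(np.ones((1, 3)), w, "void")


def test_toy_atlas_covers_six_rois_inside_brain(head):
    atlas = toy_atlas(head)
    assert set(atlas.names) == {"occipital", "fusiform", "temporal",
                                "parietal", "cingulate", "frontal"}
    for vox in atlas.rois.values():
        assert vox.shape[0] >= 1
        assert np.all(np.linalg.norm(vox - head.center, axis=1)
                      <= head.brain_radius + 1e-9)


def test_total_variance_scaling():
    x = np.array([[1.0, 3.0], [5.0, 7.0]])
    out = normalize_total_variance(x)
    assert np.std(out) == pytest.approx(1.0)
    assert np.allclose(normalize_total_variance(np.zeros((2, 2))), 0.0)
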