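"""ROI measure projection: mixing per-IC measures into anatomical regions
via truncated spherical-Gaussian dipole densities.

Each retained independent component i carries a measure M_i (an FRP
vector, a time-frequency matrix, or a single-trial epoch) and an
equivalent dipole at x_i.  Dipole-localization uncertainty is modeled by
a spherical Gaussian density of width sigma (default 12 mm) centered at
x_i and truncated at t*sigma (default t = 3), with no post-truncation
renormalization — the truncation only removes the influence of distant
dipoles.  At any brain location y the expected measure is the
density-weighted mean

    <M(y)> = sum_i P_i(y) M_i / sum_i P_i(y),

and an ROI's measure is the density-mass-weighted aggregate over its
voxels, which reduces to fixed per-(IC, ROI) weights

    w_{i,R} = sum_{y in R} P_i(y) / sum_{i'} sum_{y in R} P_{i'}(y).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .headmodel import HeadModel, standard_head

ROI_NAMES = ("occipital", "fusiform", "temporal", "parietal", "cingulate",
             "frontal")

#: Gaussian width (mm) of the dipole density
SIGMA_MM = 12.0

#: truncation multiplier: density is zero beyond TRUNCATION * sigma
TRUNCATION = 3.0


@dataclass
class ROIAtlas:
    """Named voxel-center lists (mm) on a regular grid."""

    rois: dict                   # name -> (n_voxels, 3) array
    spacing_mm: float

    def __post_init__(self) -> None:
        self.rois = {k: np.atleast_2d(np.asarray(v, dtype=float))
                     for k, v in self.rois.items()}
        for name, vox in self.rois.items():
            if vox.shape[0] < 1 or vox.shape[1] != 3:
                raise ValueError(f"ROI {name!r} needs >= 1 voxel center")

    @property
    def names(self) -> tuple:
        return tuple(self.rois)

    def stacked(self) -> tuple[np.ndarray, dict]:
        """All voxels stacked, with per-ROI index slices."""
        vox = np.vstack([self.rois[n] for n in self.names])
        slices, start = {}, 0
        for n in self.names:
            stop = start + self.rois[n].shape[0]
            slices[n] = slice(start, stop)
            start = stop
        return vox, slices

    def to_json(self, path) -> None:
        payload = {"spacing_mm": self.spacing_mm,
                   "rois": {k: v.tolist() for k, v in self.rois.items()}}
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "ROIAtlas":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(rois=payload["rois"], spacing_mm=payload["spacing_mm"])


#: stereotyped ROI sphere centers (mm) and radii for the toy atlas,
#: posterior -> anterior; temporal is bilateral
_TOY_ROIS = {
    "occipital": [((0.0, -60.0, 6.0), 18.0)],
    "fusiform": [((0.0, -46.0, -22.0), 16.0)],
    "temporal": [((-52.0, -18.0, -8.0), 15.0), ((52.0, -18.0, -8.0), 15.0)],
    "parietal": [((0.0, -34.0, 50.0), 20.0)],
    "cingulate": [((0.0, 4.0, 32.0), 14.0)],
    "frontal": [((0.0, 44.0, 26.0), 20.0)],
}


def toy_atlas(head: HeadModel | None = None, spacing: float = 8.0) -> ROIAtlas:
    """Six spherical ROIs on a regular voxel grid inside the brain volume."""
    head = head or standard_head()
    r = head.brain_radius
    ax = np.arange(-r, r + spacing / 2, spacing)
    gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
    grid = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()]) + head.center
    inside = np.linalg.norm(grid - head.center, axis=1) <= r
    grid = grid[inside]
    rois = {}
    for name, spheres in _TOY_ROIS.items():
        sel = np.zeros(grid.shape[0], dtype=bool)
        for center, radius in spheres:
            sel |= np.linalg.norm(grid - np.asarray(center), axis=1) <= radius
        rois[name] = grid[sel]
    return ROIAtlas(rois=rois, spacing_mm=spacing)


@dataclass
class DensityField:
    """Truncated-Gaussian density of each dipole at each voxel."""

    P: np.ndarray                # (n_ics, n_voxels), >= 0
    voxels: np.ndarray           # (n_voxels, 3)
    sigma: float
    truncation: float


@dataclass
class ProjectionWeights:
    """Per-(IC, ROI) mixing weights; columns with mass sum to one."""

    w: np.ndarray                # (n_ics, n_rois)
    roi_names: tuple
    roi_mass: np.ndarray         # total density mass per ROI
    empty_rois: tuple = field(default_factory=tuple)


def dipole_density(locations: np.ndarray, voxels: np.ndarray,
                   sigma: float = SIGMA_MM,
                   truncation: float = TRUNCATION) -> DensityField:
    """Evaluate the truncated spherical Gaussian of every dipole.

    P_i(y) = (2 pi sigma^2)^(-3/2) exp(-|y - x_i|^2 / (2 sigma^2)) for
    |y - x_i| <= truncation * sigma, else 0.
    """
    if sigma <= 0 or truncation <= 0:
        raise ValueError("sigma and truncation must be positive")
    locs = np.atleast_2d(np.asarray(locations, dtype=float))
    vox = np.atleast_2d(np.asarray(voxels, dtype=float))
    d2 = ((locs[:, None, :] - vox[None, :, :]) ** 2).sum(axis=2)
    norm = (2.0 * np.pi * sigma**2) ** -1.5
    P = norm * np.exp(-0.5 * d2 / sigma**2)
    P[d2 > (truncation * sigma) ** 2] = 0.0
    return DensityField(P=P, voxels=vox, sigma=sigma, truncation=truncation)


def project_at(measures: np.ndarray, density: DensityField,
               voxel_index: int) -> np.ndarray:
    """Expected measure at one voxel: density-weighted mean over ICs.

    ``measures`` has the IC axis first and is otherwise shape-agnostic.

    Raises
    ------
    ValueError
        If no dipole has density mass at the voxel.
    """
    p = density.P[:, voxel_index]
    total = p.sum()
    if total <= 0:
        raise ValueError(f"zero total density at voxel {voxel_index}")
    weights = p / total
    measures = np.asarray(measures)
    return np.tensordot(weights, measures, axes=(0, 0))


def roi_weights(density: DensityField, atlas: ROIAtlas) -> ProjectionWeights:
    """Per-ROI mixing weights from density mass overlap.

    w_{i,R} is dipole i's share of the total density mass inside ROI R;
    ROIs with zero total mass are flagged empty (their column is zero).
    """
    vox, slices = atlas.stacked()
    if vox.shape[0] != density.voxels.shape[0] or not np.allclose(
            vox, density.voxels):
        raise ValueError("density field was not evaluated on the atlas "
                         "voxels; rebuild it with atlas.stacked()[0]")
    names = atlas.names
    w = np.zeros((density.P.shape[0], len(names)))
    mass = np.zeros(len(names))
    empty = []
    for j, name in enumerate(names):
        m_i = density.P[:, slices[name]].sum(axis=1)
        mass[j] = m_i.sum()
        if mass[j] > 0:
            w[:, j] = m_i / mass[j]
        else:
            empty.append(name)
    return ProjectionWeights(w=w, roi_names=names, roi_mass=mass,
                             empty_rois=tuple(empty))


def roi_measure(measures: np.ndarray, weights: ProjectionWeights,
                roi: str) -> np.ndarray:
    """Mix per-IC measures into one ROI: sum_i w_{i,roi} M_i.

    ``measures`` has the IC axis first (e.g. ICs x trials x times); the
    result drops that axis.  Empty ROIs are rejected.
    """
    if roi in weights.empty_rois:
        raise ValueError(f"ROI {roi!r} has no density mass")
    j = weights.roi_names.index(roi)
    return np.tensordot(weights.w[:, j], np.asarray(measures), axes=(0, 0))


def normalize_total_variance(roi_traces: np.ndarray) -> np.ndarray:
    """Scale a participant's ROI measure by its total-variance SD.

    Used before grand-averaging across participants so sessions with
    different numbers of retained ICs contribute comparably; the divisor
    is the standard deviation of the concatenated time course.
    """
    x = np.asarray(roi_traces, dtype=float)
    sd = np.std(x)
    return x / sd if sd > 0 else x
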