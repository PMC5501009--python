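"""Spherical head geometry and the dipole forward model.

The simulator and the equivalent-dipole fitter share a single toy head: a
sphere of brain tissue embedded in an infinite homogeneous conductor, with
64 scalp electrodes on a spherical cap plus two mastoid reference
electrodes.  The forward model is the classic point-dipole potential in an
unbounded medium,

    v(r) = m . (r - r0) / (4 pi |r - r0|^3),

which is linear in the dipole moment ``m`` — the only property the
downstream pipeline relies on.  Anatomical realism (tissue layers, BEM) is
deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))

#: minimum admissible electrode-to-source distance (mm)
MIN_SOURCE_DISTANCE = 1.0


@dataclass(frozen=True)
class BrainVolume:
    """Spherical stand-in for the brain volume used for dipole gating."""

    center: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("brain radius must be positive")
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))

    def contains(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return np.linalg.norm(pts - self.center, axis=-1) <= self.radius


@dataclass(frozen=True)
class HeadModel:
    """Spherical head with electrode positions in mm.

    Attributes
    ----------
    center : (3,) array
        Sphere center (mm); the brain volume is centered here.
    brain_radius : float
        Radius of the brain volume (mm); neural sources live inside,
        ocular/muscular sources outside.
    electrode_positions : (n_channels, 3) array
        Electrode coordinates in mm, all at distance >= brain_radius
        from the center.
    channel_names : tuple of str
    """

    center: np.ndarray
    brain_radius: float
    electrode_positions: np.ndarray
    channel_names: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        center = np.asarray(self.center, dtype=float)
        pos = np.asarray(self.electrode_positions, dtype=float)
        object.__setattr__(self, "center", center)
        object.__setattr__(self, "electrode_positions", pos)
        if self.brain_radius <= 0:
            raise ValueError("brain_radius must be positive")
        dist = np.linalg.norm(pos - center, axis=1)
        if np.any(dist < self.brain_radius - 1e-9):
            raise ValueError("electrodes must lie outside the brain volume")

    @property
    def n_channels(self) -> int:
        return self.electrode_positions.shape[0]

    @property
    def brain_volume(self) -> BrainVolume:
        return BrainVolume(self.center, self.brain_radius)

    def scalp_indices(self) -> np.ndarray:
        """Indices of non-mastoid channels."""
        return np.array(
            [i for i, n in enumerate(self.channel_names) if not n.startswith("M")],
            dtype=int,
        )


def standard_head(
    n_scalp: int = 64,
    scalp_radius: float = 88.0,
    brain_radius: float = 65.0,
    brain_center: tuple = (0.0, 0.0, 15.0),
    with_mastoids: bool = True,
) -> HeadModel:
    """Build the default 64-channel cap (plus mastoids) on a sphere.

    Scalp electrodes are laid out on a spherical cap covering the top of
    the head down to slightly below the equator (z/R >= -0.25), spaced by
    a Fibonacci spiral for near-uniform coverage.  Mastoid electrodes sit
    low and posterior-lateral, as in a typical average-mastoid montage.
    The brain sphere is smaller than the scalp and sits above eye level,
    so periocular and nuchal generators fall outside it.
    """
    zmin, zmax = -0.25, 0.995
    k = np.arange(n_scalp)
    z = zmax - (zmax - zmin) * k / max(n_scalp - 1, 1)
    theta = k * GOLDEN_ANGLE
    rho = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    pos = scalp_radius * np.column_stack(
        [rho * np.cos(theta), rho * np.sin(theta), z]
    )
    names = [f"C{i + 1:02d}" for i in range(n_scalp)]
    if with_mastoids:
        for sign, name in ((-1.0, "M1"), (1.0, "M2")):
            m = np.array([sign * 0.72, -0.52, -0.46])
            m = scalp_radius * m / np.linalg.norm(m)
            pos = np.vstack([pos, m])
            names.append(name)
    return HeadModel(
        center=np.asarray(brain_center, dtype=float),
        brain_radius=brain_radius,
        electrode_positions=pos,
        channel_names=tuple(names),
    )


def leadfield_basis(source_location: np.ndarray, head: HeadModel) -> np.ndarray:
    """Linear map (n_channels x 3) from dipole moment to electrode potentials.

    Infinite-homogeneous-medium point dipole: row e is
    (r_e - r0) / (4 pi |r_e - r0|^3), so that v = B @ m.

    Raises
    ------
    ValueError
        If any electrode is closer than ``MIN_SOURCE_DISTANCE`` to the
        source (the potential diverges).
    """
    r0 = np.asarray(source_location, dtype=float)
    diff = head.electrode_positions - r0  # (n, 3)
    dist = np.linalg.norm(diff, axis=1)
    if np.any(dist <= MIN_SOURCE_DISTANCE):
        raise ValueError(
            "electrode coincident with (or within 1 mm of) the dipole source"
        )
    return diff / (4.0 * np.pi * dist[:, None] ** 3)


def dipole_leadfield(
    source_location: np.ndarray, moment: np.ndarray, head: HeadModel
) -> np.ndarray:
    """Electrode potentials of a current dipole; linear and odd in ``moment``."""
    moment = np.asarray(moment, dtype=float)
    return leadfield_basis(source_location, head) @ moment
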