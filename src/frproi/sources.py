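"""Source separation: ICA unmixing, equivalent-dipole fits, and exclusion
of components localizing outside the brain volume.

ICA is applied once to the whole cleaned session (it is unsupervised, so
per-fold refits would only shrink the data without guarding against
label leakage).  The decomposition contract is behavioral — independent
sources mixed linearly must be recovered (low Amari index) — rather than
fidelity to one named algorithm; the reference implementation is FastICA
with a logcosh contrast.

Each component's scalp map is then explained by a single equivalent
current dipole under the spherical forward model: a coarse grid search
over candidate locations (the optimal moment at each location is a
linear least-squares fit) followed by Nelder-Mead refinement of the
location.  Components whose best dipole falls outside the brain sphere —
corneo-retinal (EOG) and muscle (EMG) generators — are excluded from all
ROI analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from sklearn.decomposition import FastICA

from .headmodel import BrainVolume, HeadModel, leadfield_basis
from .preprocess import Recording


@dataclass
class ICSet:
    """Result of unmixing: maps, activations, explained variance.

    ``activations`` have unit variance; ``mixing[:, i]`` is component
    i's scalp map, so ``mixing @ activations + mean`` reconstructs the
    rank-retained data.
    """

    unmixing: np.ndarray         # (n_components, n_channels)
    mixing: np.ndarray           # (n_channels, n_components)
    activations: np.ndarray      # (n_components, n_samples)
    mean: np.ndarray             # (n_channels,)
    explained_variance: np.ndarray

    @property
    def n_components(self) -> int:
        return self.mixing.shape[1]

    def scalp_map(self, i: int) -> np.ndarray:
        return self.mixing[:, i]

    def reconstruct(self, include: np.ndarray | None = None) -> np.ndarray:
        """Back-project (a subset of) components to channel space."""
        if include is None:
            return self.mixing @ self.activations + self.mean[:, None]
        inc = np.asarray(include, dtype=int)
        return self.mixing[:, inc] @ self.activations[inc] + self.mean[:, None]


@dataclass
class DipoleFit:
    """Single equivalent dipole for one scalp map."""

    location: np.ndarray         # mm
    moment: np.ndarray
    residual_variance: float     # 1 - explained/total map power, in [0, 1]


def run_ica(
    rec: Recording | np.ndarray,
    n_components: int | None = None,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-4,
) -> ICSet:
    """Unmix a (high-passed) recording into unit-variance components.

    Rank-deficient data are reduced by PCA automatically (the whitening
    step); components are returned sorted by explained scalp variance,
    each sign-flipped so the largest-magnitude entry of its scalp map is
    positive (a fixed convention for the inherent ICA sign ambiguity).
    """
    data = rec.data if isinstance(rec, Recording) else np.asarray(rec)
    n_ch, n_samp = data.shape
    if n_ch >= n_samp / 10:
        raise ValueError("too few samples for a stable decomposition")
    rank = np.linalg.matrix_rank(data[:, :: max(1, n_samp // 5000)])
    k = min(n_components or n_ch, rank)
    if k < (n_components or n_ch):
        warnings.warn(f"rank-deficient data: reduced to {k} components")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence chatter on real noise
        ica = FastICA(n_components=k, whiten="unit-variance", fun="logcosh",
                      max_iter=max_iter, tol=tol, random_state=seed)
        acts = ica.fit_transform(data.T).T      # (k, n_samples), unit variance
    mixing = ica.mixing_.copy()                 # (n_ch, k)
    unmixing = ica.components_.copy()
    flip = np.sign(mixing[np.abs(mixing).argmax(axis=0), np.arange(mixing.shape[1])])
    flip[flip == 0] = 1.0
    mixing *= flip
    unmixing *= flip[:, None]
    acts *= flip[:, None]
    ev = (mixing**2).sum(axis=0)
    order = np.argsort(ev)[::-1]
    return ICSet(unmixing=unmixing[order], mixing=mixing[:, order],
                 activations=acts[order], mean=ica.mean_,
                 explained_variance=ev[order])


# ---------------------------------------------------------------------------
# equivalent-dipole fitting

_GRID_CACHE: dict = {}


def _apply_reference(B: np.ndarray, ref_rows) -> np.ndarray:
    """Re-express a leadfield in an average-of-rows reference."""
    if ref_rows is None:
        return B
    idx = np.asarray(ref_rows, dtype=int)
    return B - B[..., idx, :].mean(axis=-2, keepdims=True)


def _search_grid(head: HeadModel, spacing: float,
                 ref_rows=None) -> tuple[np.ndarray, np.ndarray]:
    """Candidate locations (inside 1.2x brain radius, 2 mm off electrodes)
    and the pseudo-inverses of their leadfield bases."""
    key = (head.electrode_positions.tobytes(), head.brain_radius, spacing,
           tuple(ref_rows) if ref_rows is not None else None)
    if key in _GRID_CACHE:
        return _GRID_CACHE[key]
    r = 1.2 * head.brain_radius
    ax = np.arange(-r, r + spacing / 2, spacing)
    gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()]) + head.center
    pts = pts[np.linalg.norm(pts - head.center, axis=1) <= r]
    dist = np.linalg.norm(
        pts[:, None, :] - head.electrode_positions[None, :, :], axis=2)
    pts = pts[dist.min(axis=1) > 2.0]
    B = np.stack([leadfield_basis(p, head) for p in pts])     # (np, n_ch, 3)
    B = _apply_reference(B, ref_rows)
    pinv = np.linalg.pinv(B)                                  # (np, 3, n_ch)
    _GRID_CACHE[key] = (pts, (B, pinv))
    return _GRID_CACHE[key]


def _rv_at(loc: np.ndarray, scalp_map: np.ndarray, head: HeadModel,
           total: float, ref_rows=None) -> float:
    try:
        B = _apply_reference(leadfield_basis(loc, head), ref_rows)
    except ValueError:
        return 1.0
    m, *_ = np.linalg.lstsq(B, scalp_map, rcond=None)
    resid = scalp_map - B @ m
    return float(resid @ resid / total)


def fit_equivalent_dipole(scalp_map: np.ndarray, head: HeadModel,
                          grid_spacing: float = 8.0,
                          refine: bool = True,
                          reference_rows=None) -> DipoleFit:
    """Best single-dipole explanation of a scalp map.

    Grid search (default 8 mm) for the location whose least-squares
    moment minimizes residual variance, then Nelder-Mead refinement of
    the location (0.1 mm tolerance).  Scaling the map rescales the
    moment but leaves location and residual variance unchanged.
    """
    scalp_map = np.asarray(scalp_map, dtype=float)
    total = float(scalp_map @ scalp_map)
    if total <= 0:
        raise ValueError("all-zero scalp map")
    pts, (B, pinv) = _search_grid(head, grid_spacing, reference_rows)
    moments = pinv @ scalp_map                                # (np, 3)
    fitted = np.einsum("pec,pc->pe", B, moments)
    rv = 1.0 - (fitted * fitted).sum(axis=1) / total
    best = int(np.argmin(rv))
    loc = pts[best]
    if refine:
        bound = 1.2 * head.brain_radius

        def objective(p):
            if np.linalg.norm(p - head.center) > bound:
                return 1.0 + np.linalg.norm(p - head.center) / bound
            return _rv_at(p, scalp_map, head, total, reference_rows)

        res = minimize(objective, loc, method="Nelder-Mead",
                       options=dict(xatol=0.1, fatol=1e-10, maxiter=400))
        if res.fun <= rv[best]:
            loc = res.x
    Bf = _apply_reference(leadfield_basis(loc, head), reference_rows)
    m, *_ = np.linalg.lstsq(Bf, scalp_map, rcond=None)
    resid = scalp_map - Bf @ m
    return DipoleFit(location=np.asarray(loc, dtype=float), moment=m,
                     residual_variance=float(np.clip(resid @ resid / total,
                                                     0.0, 1.0)))


def select_brain_ics(dipoles: list[DipoleFit],
                     volume: BrainVolume) -> np.ndarray:
    """Indices of components whose dipole lies inside the brain volume."""
    if not dipoles:
        return np.array([], dtype=int)
    locs = np.stack([d.location for d in dipoles])
    return np.flatnonzero(volume.contains(locs))
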