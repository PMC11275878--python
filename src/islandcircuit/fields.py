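"""Spatial classification of retinal boutons into island / non-island fields.

The island of mistargeted boutons is identified as the most compact
high-density component of a smoothed 3D density estimate of bouton positions
(the computational surrogate for what is identified optically as a bright,
distinct island).  The bouton-free shell separating the fields — the
exclusion zone — is measured radially from the island centroid.

All gridding, axis searching and ray casting happens in a canonical data
frame (centroid + covariance eigenvectors with moment-fixed signs), so that
labels, margins and gap statistics are equivariant under rigid motions of
the input cloud.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

__all__ = [
    "CanonicalFrame",
    "canonical_frame",
    "fibonacci_sphere",
    "mean_nearest_neighbor_spacing",
    "BoutonFieldLabeling",
    "SeparationProjection",
    "GapStatistics",
    "classify_boutons",
    "find_separation_projection",
    "measure_exclusion_zone",
]

BOUTON_LABELS = ("island", "nonisland", "ambiguous")


# --------------------------------------------------------------------------- #
# canonical frame
# --------------------------------------------------------------------------- #
@dataclass(frozen=True)
class CanonicalFrame:
    """Rigid frame derived from a point cloud (origin + orthonormal axes).

    ``rotation`` rows are the frame axes expressed in world coordinates, so
    frame coordinates are ``(P - origin) @ rotation.T``.
    """

    origin: np.ndarray
    rotation: np.ndarray

    def to_frame(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points, dtype=float) - self.origin) @ self.rotation.T

    def to_world(self, frame_points: np.ndarray) -> np.ndarray:
        return np.asarray(frame_points, dtype=float) @ self.rotation + self.origin

    def direction_to_world(self, u: np.ndarray) -> np.ndarray:
        return self.rotation.T @ np.asarray(u, dtype=float)


def canonical_frame(points: np.ndarray) -> CanonicalFrame:
    """Centroid + principal axes, with eigenvector signs fixed by the third
    central moment of the projections (rotation-equivariant)."""
    P = np.asarray(points, dtype=float)
    origin = P.mean(axis=0)
    centered = P - origin
    cov = centered.T @ centered / max(len(P) - 1, 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    axes = evecs[:, order].T  # rows = axes, descending variance
    for i in range(3):
        proj = centered @ axes[i]
        if np.sum(proj**3) < 0:
            axes[i] = -axes[i]
    if np.linalg.det(axes) < 0:
        axes[2] = -axes[2]
    return CanonicalFrame(origin=origin, rotation=axes)


def fibonacci_sphere(n: int) -> np.ndarray:
    """``(n, 3)`` near-uniform unit directions (deterministic)."""
    i = np.arange(n) + 0.5
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z**2))
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def mean_nearest_neighbor_spacing(points: np.ndarray) -> float:
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        raise ValueError("need >= 2 points for nearest-neighbor spacing")
    dist, _ = cKDTree(pts).query(pts, k=2)
    return float(dist[:, 1].mean())


# --------------------------------------------------------------------------- #
# labeling container
# --------------------------------------------------------------------------- #
@dataclass
class BoutonFieldLabeling:
    """Assignment of every retinal bouton to island / non-island / ambiguous.

    Carries the density-grid description of the island boundary (origin and
    spacing in canonical-frame coordinates, absolute density level) so that
    downstream zone tests use the same geometry as the classification.
    """

    bouton_ids: list[str]
    labels: np.ndarray  # array of strings aligned with bouton_ids
    frame: CanonicalFrame
    grid_origin: np.ndarray  # frame coords of the grid corner
    grid_spacing: float
    level: float
    component_grid: np.ndarray  # int grid, 0 = background
    island_component: int
    gap_width: float
    bandwidth: float
    level_fraction: float
    ambiguous_margin: float
    no_split: bool = False
    _label_index: dict = field(init=False, repr=False, default_factory=dict)
    _island_distance_grid: np.ndarray | None = field(init=False, repr=False, default=None)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        self._label_index = {sid: lb for sid, lb in zip(self.bouton_ids, self.labels)}

    # -- queries ---------------------------------------------------------- #
    def label_of(self, bouton_id: str) -> str:
        return self._label_index[bouton_id]

    @property
    def counts(self) -> dict:
        return {lb: int(np.sum(self.labels == lb)) for lb in BOUTON_LABELS}

    @property
    def island_mask(self) -> np.ndarray:
        return self.component_grid == self.island_component

    def island_centroid_world(self) -> np.ndarray:
        """Centroid of island-labeled boutons in world coordinates."""
        raise_if = np.sum(self.labels == "island")
        if raise_if == 0:
            raise ValueError("labeling has no island boutons")
        # stored lazily by classify_boutons
        return self._island_centroid

    def _voxel_of(self, frame_points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Voxel index per frame point and an in-grid mask."""
        X = np.atleast_2d(frame_points)
        idx = np.floor((X - self.grid_origin) / self.grid_spacing).astype(int)
        shape = np.array(self.component_grid.shape)
        inside = np.all((idx >= 0) & (idx < shape), axis=1)
        idx_clipped = np.clip(idx, 0, shape - 1)
        return idx_clipped, inside

    def _island_distance(self) -> np.ndarray:
        if self._island_distance_grid is None:
            self._island_distance_grid = ndimage.distance_transform_edt(
                ~self.island_mask, sampling=self.grid_spacing
            )
        return self._island_distance_grid

    def point_region(self, points_world: np.ndarray) -> np.ndarray:
        """Region of each world point: ``island``, ``nonisland_field``,
        ``shell`` (within ``gap_width`` of the island boundary, outside all
        components), or ``outside``."""
        X = self.frame.to_frame(np.atleast_2d(points_world))
        idx, inside = self._voxel_of(X)
        comp = self.component_grid[idx[:, 0], idx[:, 1], idx[:, 2]]
        dist = self._island_distance()[idx[:, 0], idx[:, 1], idx[:, 2]]
        out = np.full(len(X), "outside", dtype=object)
        out[inside & (comp == self.island_component)] = "island"
        out[inside & (comp > 0) & (comp != self.island_component)] = "nonisland_field"
        shell = inside & (comp == 0) & (dist > 0) & (dist <= max(self.gap_width, 0.0))
        out[shell] = "shell"
        return out

    # -- serialization ---------------------------------------------------- #
    def to_json(self, path: str | Path) -> Path:
        flat = self.component_grid.ravel()
        # run-length encode the component grid (text-friendly)
        change = np.flatnonzero(np.diff(flat)) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [len(flat)]])
        rle = []
        for s, e in zip(starts, ends):
            rle.extend([int(flat[s]), int(e - s)])
        payload = {
            "bouton_ids": list(self.bouton_ids),
            "labels": [str(lb) for lb in self.labels],
            "frame_origin": self.frame.origin.tolist(),
            "frame_rotation": self.frame.rotation.tolist(),
            "grid_origin": np.asarray(self.grid_origin).tolist(),
            "grid_spacing": float(self.grid_spacing),
            "grid_shape": list(self.component_grid.shape),
            "component_rle": rle,
            "level": float(self.level),
            "island_component": int(self.island_component),
            "gap_width": float(self.gap_width),
            "bandwidth": float(self.bandwidth),
            "level_fraction": float(self.level_fraction),
            "ambiguous_margin": float(self.ambiguous_margin),
            "no_split": bool(self.no_split),
            "island_centroid_world": self._island_centroid.tolist(),
        }
        path = Path(path)
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)
            fh.write("\n")
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "BoutonFieldLabeling":
        with open(path, "r", encoding="utf-8") as fh:
            d = json.load(fh)
        rle = d["component_rle"]
        vals = np.asarray(rle[0::2], dtype=np.int32)
        reps = np.asarray(rle[1::2], dtype=np.int64)
        grid = np.repeat(vals, reps).reshape(d["grid_shape"])
        obj = cls(
            bouton_ids=d["bouton_ids"],
            labels=np.asarray(d["labels"], dtype=object),
            frame=CanonicalFrame(
                origin=np.asarray(d["frame_origin"]),
                rotation=np.asarray(d["frame_rotation"]),
            ),
            grid_origin=np.asarray(d["grid_origin"]),
            grid_spacing=d["grid_spacing"],
            level=d["level"],
            component_grid=grid,
            island_component=d["island_component"],
            gap_width=d["gap_width"],
            bandwidth=d["bandwidth"],
            level_fraction=d["level_fraction"],
            ambiguous_margin=d["ambiguous_margin"],
            no_split=d["no_split"],
        )
        obj._island_centroid = np.asarray(d["island_centroid_world"])
        return obj


def _in_convex_hull(points: np.ndarray, queries: np.ndarray) -> np.ndarray:
    """Boolean mask of query points inside the convex hull of ``points``.

    Falls back to the bounding box for degenerate (flat) clouds.
    """
    from scipy.spatial import ConvexHull, Delaunay, QhullError

    try:
        hull = ConvexHull(points)
        tri = Delaunay(points[hull.vertices])
        return tri.find_simplex(queries) >= 0
    except QhullError:
        lo, hi = points.min(axis=0), points.max(axis=0)
        return np.all((queries >= lo) & (queries <= hi), axis=1)


# --------------------------------------------------------------------------- #
# classification
# --------------------------------------------------------------------------- #
def classify_boutons(
    positions: np.ndarray,
    bandwidth: float | None = None,
    level_fraction: float = 0.1,
    ids: list[str] | None = None,
    grid_spacing: float | None = None,
    ambiguous_margin: float | None = None,
    max_voxels: int = 2_000_000,
) -> BoutonFieldLabeling:
    """Classify bouton positions into island / non-island / ambiguous.

    Procedure: histogram the positions on a regular grid in the canonical
    frame, smooth with a Gaussian kernel of s.d. ``bandwidth`` (default: 2x
    the mean nearest-neighbor spacing), correct for the finite support of the
    cloud, threshold at ``level_fraction`` of the peak density, and take
    26-connected components.  The most compact component (smallest
    voxel-volume-to-bouton-count ratio) is the island; boutons in other
    components are non-island.  Boutons below threshold adopt the nearest
    component's field when it lies within ``ambiguous_margin`` (default: half
    a bandwidth) and are otherwise ambiguous — mid-gap boutons stay
    ambiguous, low-density fluctuations inside a field do not orphan their
    boutons.

    If all boutons fall in a single component the labeling is returned with
    ``no_split=True`` rather than raising; the caller decides.
    """
    P = np.asarray(positions, dtype=float)
    if P.ndim != 2 or P.shape[1] != 3 or len(P) < 2:
        raise ValueError("need >= 2 bouton positions of shape (n, 3)")
    if ids is None:
        ids = [f"b{i:06d}" for i in range(len(P))]
    if len(ids) != len(P):
        raise ValueError("ids and positions length mismatch")

    frame = canonical_frame(P)
    X = frame.to_frame(P)
    if bandwidth is None:
        bandwidth = 2.0 * mean_nearest_neighbor_spacing(P)
    if bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")
    if ambiguous_margin is None:
        ambiguous_margin = 0.5 * bandwidth
    spacing = grid_spacing if grid_spacing is not None else bandwidth / 2.0

    lo_data, hi_data = X.min(axis=0), X.max(axis=0)
    pad = 3.0 * bandwidth
    lo, hi = lo_data - pad, hi_data + pad
    n_bins = np.maximum(np.ceil((hi - lo) / spacing).astype(int), 4)
    while int(np.prod(n_bins)) > max_voxels:
        spacing *= 1.26  # ~double the voxel volume
        n_bins = np.maximum(np.ceil((hi - lo) / spacing).astype(int), 4)
    edges = [lo[a] + np.arange(n_bins[a] + 1) * spacing for a in range(3)]
    counts, _ = np.histogramdd(X, bins=edges)

    sigma_vox = bandwidth / spacing
    smoothed = ndimage.gaussian_filter(counts, sigma_vox, mode="constant")
    # support correction: renormalize by the smoothed indicator of the cloud's
    # convex hull, so field density does not fall off at the cloud's edges
    centers = [lo[a] + (np.arange(n_bins[a]) + 0.5) * spacing for a in range(3)]
    cx, cy, cz = np.meshgrid(*centers, indexing="ij")
    voxel_centers = np.column_stack([cx.ravel(), cy.ravel(), cz.ravel()])
    mask = _in_convex_hull(X, voxel_centers).reshape(counts.shape).astype(float)
    corr = ndimage.gaussian_filter(mask, sigma_vox, mode="constant")
    density = np.where(corr > 0.05, smoothed / np.maximum(corr, 0.05), 0.0)

    level = level_fraction * float(density.max())
    above = density >= level
    comp_grid, n_comp = ndimage.label(above, structure=np.ones((3, 3, 3), dtype=int))

    vox = np.floor((X - lo) / spacing).astype(int)
    vox = np.clip(vox, 0, np.asarray(comp_grid.shape) - 1)
    comp_of_bouton = comp_grid[vox[:, 0], vox[:, 1], vox[:, 2]]

    bouton_counts = np.bincount(comp_of_bouton, minlength=n_comp + 1)
    voxel_counts = np.bincount(comp_grid.ravel(), minlength=n_comp + 1)
    candidates = [c for c in range(1, n_comp + 1) if bouton_counts[c] > 0]
    if not candidates:
        raise ValueError("density thresholding produced no populated component")
    # island = most compact populated component; deterministic tie-break
    island_comp = min(
        candidates, key=lambda c: (voxel_counts[c] / bouton_counts[c], -bouton_counts[c], c)
    )
    no_split = len(candidates) == 1

    # fall back to the nearest component within the ambiguity margin
    background = comp_grid == 0
    if background.any() and n_comp > 0:
        dist_bg, nearest_idx = ndimage.distance_transform_edt(
            background, sampling=spacing, return_indices=True
        )
        nearest_comp = comp_grid[
            nearest_idx[0], nearest_idx[1], nearest_idx[2]
        ]
    else:
        dist_bg = np.zeros_like(comp_grid, dtype=float)
        nearest_comp = comp_grid

    labels = np.empty(len(P), dtype=object)
    for i in range(len(P)):
        c = comp_of_bouton[i]
        if c == 0:
            d = dist_bg[vox[i, 0], vox[i, 1], vox[i, 2]]
            if d <= ambiguous_margin:
                c = nearest_comp[vox[i, 0], vox[i, 1], vox[i, 2]]
        if c == 0:
            labels[i] = "ambiguous"
        elif c == island_comp:
            labels[i] = "island"
        else:
            labels[i] = "nonisland"

    labeling = BoutonFieldLabeling(
        bouton_ids=list(ids),
        labels=labels,
        frame=frame,
        grid_origin=lo,
        grid_spacing=spacing,
        level=level,
        component_grid=comp_grid.astype(np.int32),
        island_component=int(island_comp),
        gap_width=0.0,
        bandwidth=float(bandwidth),
        level_fraction=float(level_fraction),
        ambiguous_margin=float(ambiguous_margin),
        no_split=no_split,
    )
    labeling._island_centroid = P[labels == "island"].mean(axis=0)
    if not no_split:
        labeling.gap_width = _grid_gap_width(labeling)
    return labeling


def _grid_gap_width(labeling: BoutonFieldLabeling, n_rays: int = 128) -> float:
    """Median background thickness between the island component and the other
    components, by ray marching from the island component's center of mass."""
    grid = labeling.component_grid
    island = labeling.island_mask
    com = np.asarray(ndimage.center_of_mass(island))
    step = 0.5
    max_steps = int(np.ceil(np.linalg.norm(grid.shape) / step)) + 1
    dirs = fibonacci_sphere(n_rays)
    gaps = []
    t = (np.arange(1, max_steps) * step)[:, None]
    for u in dirs:
        pts = com[None, :] + t * u[None, :]
        idx = np.round(pts).astype(int)
        inside = np.all((idx >= 0) & (idx < np.asarray(grid.shape)), axis=1)
        idx = idx[inside]
        if len(idx) == 0:
            continue
        vals = grid[idx[:, 0], idx[:, 1], idx[:, 2]]
        is_isl = vals == labeling.island_component
        is_other = (vals > 0) & ~is_isl
        if not is_isl.any() or not is_other.any():
            continue
        last_isl = np.flatnonzero(is_isl)[-1]
        after = np.flatnonzero(is_other & (np.arange(len(vals)) > last_isl))
        if len(after) == 0:
            continue
        gaps.append((after[0] - last_isl) * step * labeling.grid_spacing)
    return float(np.median(gaps)) if gaps else 0.0


# --------------------------------------------------------------------------- #
# separation projection
# --------------------------------------------------------------------------- #
@dataclass
class SeparationProjection:
    """Axis (and rotation) giving the clearest 1D island/non-island split.

    ``margin`` is the 1D gap between the projected supports of the two
    classes along ``axis`` (0 when they interpenetrate, with
    ``overlap_count`` points inside the overlapping interval).  ``axis``
    points from the island side toward the non-island side.
    """

    rotation: np.ndarray
    axis: np.ndarray
    margin: float
    overlap_count: int

    def project(self, points: np.ndarray) -> np.ndarray:
        """2D coordinates (separation axis first) for plotting."""
        return np.asarray(points, dtype=float) @ self.rotation[:2].T

    def to_dict(self) -> dict:
        return {
            "rotation": self.rotation.tolist(),
            "axis": self.axis.tolist(),
            "margin_nm": float(self.margin),
            "overlap_count": int(self.overlap_count),
        }


def _margin_raw(u: np.ndarray, A: np.ndarray, B: np.ndarray) -> float:
    """Signed 1D margin between projected supports (negative = overlap)."""
    pa = A @ u
    pb = B @ u
    return float(max(pb.min() - pa.max(), pa.min() - pb.max()))


def _golden_section_max(f, a: float, b: float, tol: float) -> float:
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    c, d = b - invphi * (b - a), a + invphi * (b - a)
    fc, fd = f(c), f(d)
    while abs(b - a) > tol:
        if fc < fd:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
        else:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
    return (a + b) / 2.0


def find_separation_projection(
    labeling: BoutonFieldLabeling,
    positions: np.ndarray,
    angular_resolution: float = 3.0,
) -> SeparationProjection:
    """Search unit axes for the one maximizing the 1D separation margin
    between projected island and non-island boutons (ambiguous excluded).

    A Fibonacci-sphere grid at ``angular_resolution`` (degrees) is refined by
    alternating golden-section search on the two spherical angles.  Ties at
    the grid stage break toward the lexicographically smallest axis.
    Deterministic; no randomness.
    """
    P = np.asarray(positions, dtype=float)
    if len(P) != len(labeling.labels):
        raise ValueError("positions must align with the labeling")
    isl = labeling.labels == "island"
    non = labeling.labels == "nonisland"
    if not isl.any() or not non.any():
        raise ValueError("both island and non-island classes must be non-empty")
    X = labeling.frame.to_frame(P)
    A, B = X[isl], X[non]

    res_rad = np.deg2rad(angular_resolution)
    n_axes = max(64, int(np.ceil(4.0 * np.pi / res_rad**2)))
    axes = fibonacci_sphere(n_axes)
    margins = np.empty(n_axes)
    chunk = max(1, int(2e7 // max(len(A) + len(B), 1)))
    for s in range(0, n_axes, chunk):
        blk = axes[s : s + chunk]
        pa = A @ blk.T
        pb = B @ blk.T
        margins[s : s + len(blk)] = np.maximum(
            pb.min(axis=0) - pa.max(axis=0), pa.min(axis=0) - pb.max(axis=0)
        )
    best = margins.max()
    cand = np.flatnonzero(margins >= best - 1e-12)
    cand = cand[np.lexsort((axes[cand, 2], axes[cand, 1], axes[cand, 0]))]
    u0 = axes[cand[0]]

    theta0 = float(np.arccos(np.clip(u0[2], -1, 1)))
    phi0 = float(np.arctan2(u0[1], u0[0]))

    def from_angles(theta: float, phi: float) -> np.ndarray:
        st = np.sin(theta)
        return np.array([st * np.cos(phi), st * np.sin(phi), np.cos(theta)])

    theta, phi = theta0, phi0
    span = 2.0 * res_rad
    for _ in range(2):
        theta = _golden_section_max(
            lambda t: _margin_raw(from_angles(t, phi), A, B),
            theta - span,
            theta + span,
            res_rad / 50.0,
        )
        phi = _golden_section_max(
            lambda p: _margin_raw(from_angles(theta, p), A, B),
            phi - span,
            phi + span,
            res_rad / 50.0,
        )
        span /= 4.0
    u = from_angles(theta, phi)
    raw = _margin_raw(u, A, B)
    if raw < best:  # refinement must never lose to the grid
        u, raw = u0, best

    # orient: island side low, non-island side high
    pa, pb = A @ u, B @ u
    if pb.min() - pa.max() < pa.min() - pb.max():
        u = -u
        pa, pb = -pa, -pb
    overlap_count = 0
    if raw < 0:
        lo_ov, hi_ov = pb.min(), pa.max()
        overlap_count = int(np.sum((pa >= lo_ov) & (pa <= hi_ov))) + int(
            np.sum((pb >= lo_ov) & (pb <= hi_ov))
        )

    axis_world = labeling.frame.direction_to_world(u)
    axis_world /= np.linalg.norm(axis_world)
    # complete to a right-handed orthonormal rotation (rows)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, axis_world)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e2 = helper - np.dot(helper, axis_world) * axis_world
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(axis_world, e2)
    rotation = np.vstack([axis_world, e2, e3])
    return SeparationProjection(
        rotation=rotation,
        axis=axis_world,
        margin=float(max(raw, 0.0)),
        overlap_count=overlap_count,
    )


# --------------------------------------------------------------------------- #
# exclusion zone
# --------------------------------------------------------------------------- #
@dataclass
class GapStatistics:
    """Radial thickness of the bouton-free shell around the island."""

    median_nm: float
    min_nm: float
    max_nm: float
    n_rays: int
    n_excluded: int
    no_zone: bool

    def to_dict(self) -> dict:
        return {
            "median_nm": float(self.median_nm),
            "min_nm": float(self.min_nm),
            "max_nm": float(self.max_nm),
            "n_rays": int(self.n_rays),
            "n_excluded": int(self.n_excluded),
            "no_zone": bool(self.no_zone),
        }


def measure_exclusion_zone(
    labeling: BoutonFieldLabeling,
    positions: np.ndarray,
    n_rays: int = 300,
    tube_radius: float | None = None,
) -> GapStatistics:
    """Measure the shell between fields by casting rays from the island
    bouton centroid through a uniform direction sample.

    Along each ray, the gap is the distance from the last island bouton to
    the first non-island bouton, considering boutons within ``tube_radius``
    (default: one bandwidth) of the ray.  Rays meeting no non-island bouton
    past the island are excluded and counted.  ``no_zone`` flags a median gap
    below one bandwidth (≈ the resolvable inter-bouton spacing).
    """
    P = np.asarray(positions, dtype=float)
    if len(P) != len(labeling.labels):
        raise ValueError("positions must align with the labeling")
    isl = labeling.labels == "island"
    non = labeling.labels == "nonisland"
    if not isl.any() or not non.any():
        raise ValueError("labeling must contain both fields")
    if tube_radius is None:
        tube_radius = labeling.bandwidth

    X = labeling.frame.to_frame(P)
    center = X[isl].mean(axis=0)
    Yi = X[isl] - center
    Yn = X[non] - center
    dirs = fibonacci_sphere(n_rays)
    gaps = []
    excluded = 0
    r2 = tube_radius**2
    ni2 = np.einsum("ij,ij->i", Yi, Yi)
    nn2 = np.einsum("ij,ij->i", Yn, Yn)
    for u in dirs:
        ti = Yi @ u
        sel_i = (ti > 0) & (ni2 - ti**2 <= r2)
        if not sel_i.any():
            excluded += 1
            continue
        t_last = ti[sel_i].max()
        tn = Yn @ u
        sel_n = (tn > t_last) & (nn2 - tn**2 <= r2)
        if not sel_n.any():
            excluded += 1
            continue
        gaps.append(float(tn[sel_n].min() - t_last))
    if not gaps:
        return GapStatistics(0.0, 0.0, 0.0, n_rays, excluded, True)
    gaps = np.asarray(gaps)
    median = float(np.median(gaps))
    return GapStatistics(
        median_nm=median,
        min_nm=float(gaps.min()),
        max_nm=float(gaps.max()),
        n_rays=n_rays,
        n_excluded=excluded,
        no_zone=median < labeling.bandwidth,
    )
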