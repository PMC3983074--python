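"""Docking-volume definition: cavity mapping and distance queries.

Two mapping algorithms define the boolean cavity lattice:

* reference-ligand: accessible volume within a radius of a known bound
  ligand's heavy atoms;
* two-probe-sphere: volume reachable by a small probe but sheltered from
  bulk solvent, where "open" space is what a large probe can reach when
  rolled in from the boundary of the search sphere.

Grid spacing defaults to 0.5 A; steric accessibility uses per-element
Bondi-style vdW radii plus a solvent-probe allowance of 1.4 A.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .model import Ligand, Receptor
from .params import vdw_radius

__all__ = ["CavityGrid", "map_reference_ligand", "map_two_sphere",
           "distance_to_cavity", "save_cavity", "load_cavity"]

DEFAULT_SPACING = 0.5
PROBE_ALLOWANCE = 1.4


class EmptyCavityError(ValueError):
    pass


@dataclass
class CavityGrid:
    """Boolean occupancy lattice of the docking volume.

    ``distance_to_cavity`` queries are exact nearest-inside-grid-point
    distances (KD-tree over the inside points), 0 for points within half a
    spacing of an inside point.
    """

    origin: np.ndarray       # (3,) corner of the lattice, Angstrom
    spacing: float
    inside: np.ndarray       # boolean (nx, ny, nz)

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        idx = np.argwhere(self.inside)
        self.cavity_points = self.origin + idx * self.spacing
        self._tree = cKDTree(self.cavity_points) if len(idx) else None

    @property
    def shape(self):
        return self.inside.shape

    @property
    def n_inside(self) -> int:
        return int(self.inside.sum())

    @property
    def volume(self) -> float:
        """Inside-point count x spacing^3, Angstrom^3."""
        return self.n_inside * self.spacing ** 3

    def distances(self, points: np.ndarray) -> np.ndarray:
        """Distance from each query point to the nearest inside grid point."""
        if self._tree is None:
            raise EmptyCavityError("cavity has no inside points")
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        d, _ = self._tree.query(pts)
        return np.where(d <= 0.5 * self.spacing, 0.0, d)


def distance_to_cavity(grid: CavityGrid, p) -> float:
    """0 within half a spacing of an inside point, else exact distance to the
    nearest inside grid point (points outside the lattice allowed)."""
    return float(grid.distances(np.asarray(p, dtype=float).reshape(1, 3))[0])


def _lattice(lo: np.ndarray, hi: np.ndarray, spacing: float):
    shape = np.maximum(np.ceil((hi - lo) / spacing).astype(int) + 1, 1)
    axes = [lo[k] + spacing * np.arange(shape[k]) for k in range(3)]
    return shape, axes


def _steric_free(axes, rec_coords, rec_radii, allowance) -> np.ndarray:
    """True where no receptor heavy atom is closer than vdw_r + allowance.

    Stamped sphere-by-sphere over local index windows, so cost scales with
    the receptor size, not with grid points x atoms.
    """
    shape = tuple(len(a) for a in axes)
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([gx, gy, gz], axis=-1)
    free = np.ones(shape, dtype=bool)
    lo = np.array([a[0] for a in axes])
    spacing = axes[0][1] - axes[0][0] if len(axes[0]) > 1 else 1.0
    for xj, rj in zip(rec_coords, rec_radii):
        cut = rj + allowance
        imin = np.maximum(np.floor((xj - cut - lo) / spacing).astype(int), 0)
        imax = np.minimum(np.ceil((xj + cut - lo) / spacing).astype(int) + 1, shape)
        if np.any(imin >= imax):
            continue
        sl = tuple(slice(a, b) for a, b in zip(imin, imax))
        local = pts[sl] - xj
        free[sl] &= (local ** 2).sum(axis=-1) >= cut * cut
    return free, pts


def _receptor_heavy(rec: Receptor):
    mol = rec.molecule
    mask = mol.heavy_mask
    coords = mol.coords[mask]
    radii = np.array([vdw_radius(e) for e, h in zip(mol.elements, mask) if h])
    return coords, radii


def _keep_components(inside: np.ndarray, seed_mask: np.ndarray) -> np.ndarray:
    """Keep connected components (6-connectivity) overlapping the seed mask."""
    labels, n = ndimage.label(inside)
    if n == 0:
        return inside
    keep = np.unique(labels[seed_mask & (labels > 0)])
    return np.isin(labels, keep[keep > 0])


def map_reference_ligand(rec: Receptor, ref: Ligand, radius: float = 6.0,
                         spacing: float = DEFAULT_SPACING,
                         probe_allowance: float = PROBE_ALLOWANCE) -> CavityGrid:
    """Accessible volume within ``radius`` of the reference ligand.

    A grid point is inside iff it lies within ``radius`` of any reference
    heavy atom and no receptor heavy atom is closer than its vdW radius plus
    the probe allowance.  Connected components that do not overlap the
    reference ligand (within one radius shell of its atoms) are discarded.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    ref_heavy = ref.molecule.coords[ref.molecule.heavy_mask]
    if len(ref_heavy) == 0:
        raise ValueError("reference ligand has no heavy atoms")
    lo = ref_heavy.min(axis=0) - radius
    hi = ref_heavy.max(axis=0) + radius
    shape, axes = _lattice(lo, hi, spacing)
    rec_coords, rec_radii = _receptor_heavy(rec)
    free, pts = _steric_free(axes, rec_coords, rec_radii, probe_allowance)
    tree = cKDTree(ref_heavy)
    d_ref, _ = tree.query(pts.reshape(-1, 3))
    near = (d_ref <= radius).reshape(shape)
    inside = free & near
    seed = (d_ref <= max(2.0, spacing)).reshape(shape) & inside
    if seed.any():
        inside = _keep_components(inside, seed)
    if not inside.any():
        raise EmptyCavityError("no accessible volume within the reference radius")
    return CavityGrid(lo, spacing, inside)


def map_two_sphere(rec: Receptor, center, search_radius: float = 10.0,
                   r_large: float = 6.0, r_small: float = 1.5,
                   spacing: float = DEFAULT_SPACING) -> CavityGrid:
    """Two-probe-sphere mapping around ``center``.

    Points accessible to the small probe but sheltered from bulk solvent are
    kept: the large probe is rolled in from the boundary of the search
    sphere (flood fill through large-probe-accessible space, then dilation
    by the large-probe radius marks "open" solvent); inside = small-probe
    accessible AND NOT open.  Components are kept only if within
    ``search_radius`` of the center.
    """
    if not (r_large > r_small > 0):
        raise ValueError("need r_large > r_small > 0")
    center = np.asarray(center, dtype=float)
    lo = center - search_radius
    hi = center + search_radius
    shape, axes = _lattice(lo, hi, spacing)
    rec_coords, rec_radii = _receptor_heavy(rec)
    small_free, pts = _steric_free(axes, rec_coords, rec_radii, r_small)
    large_free, _ = _steric_free(axes, rec_coords, rec_radii, r_large)

    r = np.linalg.norm(pts - center, axis=-1)
    in_sphere = r <= search_radius
    boundary = large_free & (r >= search_radius - 2 * spacing)
    # flood fill: large-probe centres reachable from the boundary
    labels, n = ndimage.label(large_free)
    open_centers = np.zeros(shape, dtype=bool)
    if n:
        reach = np.unique(labels[boundary & (labels > 0)])
        open_centers = np.isin(labels, reach[reach > 0])
    # dilate probe centres by the large-probe radius -> open solvent volume
    if open_centers.any():
        dist_vox = ndimage.distance_transform_edt(~open_centers)
        open_space = dist_vox * spacing <= r_large
    else:
        open_space = np.zeros(shape, dtype=bool)

    inside = small_free & ~open_space & in_sphere
    if not inside.any():
        raise EmptyCavityError("two-sphere mapping found no sheltered volume")
    # keep the connected component closest to the requested center (the
    # finite search sphere can create spurious sheltered shards at its rim)
    labels, n = ndimage.label(inside)
    best_label, best_d = 0, np.inf
    for lab in range(1, n + 1):
        d = r[labels == lab].min()
        if d < best_d:
            best_label, best_d = lab, d
    inside = labels == best_label
    return CavityGrid(lo, spacing, inside)


def save_cavity(grid: CavityGrid, path) -> None:
    """Portable cavity container: JSON header + packed boolean lattice."""
    header = {"origin": grid.origin.tolist(), "spacing": grid.spacing,
              "shape": list(grid.shape)}
    np.savez(path, header=json.dumps(header),
             inside=np.packbits(grid.inside.astype(np.uint8)))


def load_cavity(path) -> CavityGrid:
    with np.load(path, allow_pickle=False) as data:
        header = json.loads(str(data["header"]))
        shape = tuple(header["shape"])
        n = shape[0] * shape[1] * shape[2]
        inside = np.unpackbits(data["inside"])[:n].reshape(shape).astype(bool)
    return CavityGrid(np.array(header["origin"]), float(header["spacing"]), inside)
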