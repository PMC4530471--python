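"""Density maps: simulation from atomic models, Laplacian filtering,
map-map correlation, and MRC/CCP4 I/O.

Grid convention: ``values[i, j, k]`` is the voxel whose *center* sits at
``origin + voxel_size * (i, j, k)`` — X is the first (fastest-varying on
disk) index. Maps are written as mode-2 (float32) CCP4 files with the
origin stored in header words 50-52.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import gemmi
from scipy import ndimage

from .errors import DegenerateGeometryError, EmptySelectionError, SamplingError, UndefinedCorrelationError
from .structure import AtomicStructure, atomic_number

# FWHM = sigma * 2*sqrt(2 ln 2)
_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
# Gaussian kernel cutoff in units of sigma; 4 sigma keeps >99.8% of the
# 3D mass so discrete integrals match atomic numbers to well under 1%.
_CUTOFF_SIGMAS = 4.0


@dataclass
class DensityMap:
    """A 3D scalar grid with isotropic voxel size and origin in Å."""

    values: np.ndarray
    voxel_size: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    resolution_label: float | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise DegenerateGeometryError("density grid must be 3D with >=1 voxel per axis")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("density values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def voxel_centers_axis(self, axis: int) -> np.ndarray:
        n = self.values.shape[axis]
        return self.origin[axis] + self.voxel_size * np.arange(n)

    def same_grid(self, other: "DensityMap") -> bool:
        return (
            self.values.shape == other.values.shape
            and np.isclose(self.voxel_size, other.voxel_size)
            and np.allclose(self.origin, other.origin, atol=1e-6)
        )

    def copy_with(self, values: np.ndarray) -> "DensityMap":
        return DensityMap(values=values, voxel_size=self.voxel_size,
                          origin=self.origin.copy(),
                          resolution_label=self.resolution_label)


def _splat_gaussians(values: np.ndarray, origin: np.ndarray, voxel: float,
                     coords: np.ndarray, weights: np.ndarray, sigma: float) -> None:
    """Accumulate normalized 3D Gaussians (integral = weight) into the grid."""
    nx, ny, nz = values.shape
    half = int(np.ceil(_CUTOFF_SIGMAS * sigma / voxel))
    norm = (2.0 * np.pi * sigma * sigma) ** -1.5
    inv2s2 = 1.0 / (2.0 * sigma * sigma)
    offs = np.arange(-half, half + 1)
    for xyz, w in zip(coords, weights):
        ic = np.round((xyz - origin) / voxel).astype(int)
        lo = np.maximum(ic - half, 0)
        hi = np.minimum(ic + half, [nx - 1, ny - 1, nz - 1])
        if np.any(lo > hi):
            continue
        ax = origin[0] + voxel * np.arange(lo[0], hi[0] + 1) - xyz[0]
        ay = origin[1] + voxel * np.arange(lo[1], hi[1] + 1) - xyz[1]
        az = origin[2] + voxel * np.arange(lo[2], hi[2] + 1) - xyz[2]
        gx = np.exp(-ax * ax * inv2s2)
        gy = np.exp(-ay * ay * inv2s2)
        gz = np.exp(-az * az * inv2s2)
        values[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1] += (
            w * norm * gx[:, None, None] * gy[None, :, None] * gz[None, None, :]
        )


def simulate_map(structure: AtomicStructure, resolution: float,
                 voxel_size: float, padding: float = 5.0) -> DensityMap:
    """Blur an atomic structure to a stated resolution.

    Every heavy atom contributes an isotropic Gaussian with
    FWHM = ``resolution`` and total integral equal to its atomic number;
    the grid spans the heavy-atom bounding box plus ``padding`` on all
    sides. Requires resolution >= 2 * voxel_size (Nyquist).
    """
    if resolution < 2.0 * voxel_size:
        raise SamplingError(
            f"resolution {resolution} Å undersampled at voxel {voxel_size} Å "
            "(need resolution >= 2*voxel_size)")
    atoms = structure.heavy_atoms()
    if not atoms:
        raise EmptySelectionError("cannot simulate a map from an empty structure")
    coords = np.array([a.coord for a in atoms])
    weights = np.array([float(atomic_number(a.element)) for a in atoms])
    lo = coords.min(axis=0) - padding
    hi = coords.max(axis=0) + padding
    shape = tuple(int(np.floor((hi[i] - lo[i]) / voxel_size)) + 1 for i in range(3))
    values = np.zeros(shape)
    sigma = resolution * _FWHM_TO_SIGMA
    _splat_gaussians(values, lo, voxel_size, coords, weights, sigma)
    return DensityMap(values=values, voxel_size=voxel_size, origin=lo,
                      resolution_label=resolution)


def simulate_on_grid(structure: AtomicStructure, resolution: float,
                     like: DensityMap) -> DensityMap:
    """Blur a structure onto an existing map's grid geometry."""
    atoms = structure.heavy_atoms()
    if not atoms:
        raise EmptySelectionError("cannot simulate a map from an empty structure")
    coords = np.array([a.coord for a in atoms])
    weights = np.array([float(atomic_number(a.element)) for a in atoms])
    values = np.zeros(like.values.shape)
    sigma = resolution * _FWHM_TO_SIGMA
    _splat_gaussians(values, like.origin, like.voxel_size, coords, weights, sigma)
    return DensityMap(values=values, voxel_size=like.voxel_size,
                      origin=like.origin.copy(), resolution_label=resolution)


_LAPLACIAN_KERNEL = np.zeros((3, 3, 3))
_LAPLACIAN_KERNEL[1, 1, 1] = -6.0
for _d in range(3):
    for _s in (0, 2):
        _idx = [1, 1, 1]
        _idx[_d] = _s
        _LAPLACIAN_KERNEL[tuple(_idx)] = 1.0


def laplacian_filter(density_map: DensityMap) -> DensityMap:
    """Discrete 6-neighbour Laplacian (unit lattice spacing).

    Boundary voxels replicate the edge value, so the defining property of
    the Laplacian — constant maps filter to exactly zero — holds on the
    whole grid, not just the interior.
    """
    if min(density_map.values.shape) < 3:
        raise DegenerateGeometryError("Laplacian requires >= 3 voxels per axis")
    filtered = ndimage.convolve(density_map.values, _LAPLACIAN_KERNEL,
                                mode="nearest")
    return density_map.copy_with(filtered)


def resample_onto(map_b: DensityMap, like: DensityMap) -> DensityMap:
    """Trilinear resampling of map_b onto like's grid (like is authoritative)."""
    idx = [
        (like.voxel_centers_axis(ax)[:, None] - map_b.origin[ax]) / map_b.voxel_size
        for ax in range(3)
    ]
    gi, gj, gk = np.meshgrid(idx[0].ravel(), idx[1].ravel(), idx[2].ravel(),
                             indexing="ij")
    vals = ndimage.map_coordinates(map_b.values, [gi, gj, gk], order=1,
                                   mode="constant", cval=0.0)
    return DensityMap(values=vals, voxel_size=like.voxel_size,
                      origin=like.origin.copy(),
                      resolution_label=map_b.resolution_label)


def cross_correlation(map_a: DensityMap, map_b: DensityMap,
                      mask_mode: str = "full") -> float:
    """Pearson correlation between two maps over a voxel mask.

    ``full`` correlates every voxel; ``model_support`` restricts to voxels
    where map_b exceeds 10% of its maximum. map_b is resampled onto map_a's
    grid by trilinear interpolation when geometries differ.
    """
    if mask_mode not in ("full", "model_support"):
        raise ValueError(f"unknown mask_mode {mask_mode!r}")
    if not map_a.same_grid(map_b):
        map_b = resample_onto(map_b, map_a)
    a = map_a.values.ravel()
    b = map_b.values.ravel()
    if mask_mode == "model_support":
        mask = b > 0.1 * b.max()
        a, b = a[mask], b[mask]
    if a.size == 0:
        raise UndefinedCorrelationError("empty correlation mask")
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        raise UndefinedCorrelationError("zero variance in masked region")
    return float(np.clip((a @ b) / denom, -1.0, 1.0))


def write_mrc(density_map: DensityMap, path) -> str:
    """Write a mode-2 (float32) CCP4/MRC map; origin in header words 50-52."""
    grid = gemmi.FloatGrid(*density_map.values.shape)
    np.array(grid, copy=False)[:] = density_map.values.astype(np.float32)
    n = density_map.values.shape
    grid.set_unit_cell(gemmi.UnitCell(
        n[0] * density_map.voxel_size, n[1] * density_map.voxel_size,
        n[2] * density_map.voxel_size, 90, 90, 90))
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = grid
    ccp4.update_ccp4_header()
    for word, val in zip((50, 51, 52), density_map.origin):
        ccp4.set_header_float(word, float(np.float32(val)))
    ccp4.write_ccp4_map(str(path))
    return str(path)


def read_mrc(path) -> DensityMap:
    """Read an MRC/CCP4 map, normalizing axis order to X-fastest.

    The origin is taken from header words 50-52, falling back to
    start-index x voxel when those are all zero.
    """
    ccp4 = gemmi.read_ccp4_map(str(path))
    ccp4.setup(float("nan"), gemmi.MapSetup.ReorderOnly)
    values = np.array(ccp4.grid, copy=True).astype(float)
    spacing = ccp4.grid.spacing
    voxel = float(spacing[0])
    origin = np.array([ccp4.header_float(w) for w in (50, 51, 52)], dtype=float)
    if np.all(origin == 0):
        starts = [ccp4.header_i32(w) for w in (5, 6, 7)]
        origin = np.array(starts, dtype=float) * voxel
    return DensityMap(values=values, voxel_size=voxel, origin=origin)
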