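"""Exhaustive rigid-body docking of an atomic structure into a density map.

The six-dimensional search enumerates a deterministic, near-uniform grid of
orientations (super-Fibonacci sampling of the quaternion hemisphere, sized
so the covering radius matches the requested angular step) and, for each
orientation, scans all translations at voxel granularity by FFT
cross-correlation between the blurred probe and the target map. Scores are
Pearson correlations, so they are invariant to intensity scaling of either
map. With Laplacian filtering enabled, both the target and the probe map
are filtered before correlation, which penalizes mismatches in surface
features. Hits are clustered and ranked by correlation; normalized scores
divide by the top hit so hit 1 always has normalized_cc = 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .density import (
    DensityMap,
    _FWHM_TO_SIGMA,
    _splat_gaussians,
    cross_correlation,
    laplacian_filter,
    simulate_on_grid,
)
from .errors import DegenerateGeometryError, EmptySelectionError
from .structure import AtomicStructure, atomic_number

# Empirical covering constant of the super-Fibonacci orientation grid:
# covering radius ~ (K / n)^(1/3) radians.
_SO3_COVERING_K = 60.0


def quat_to_matrix(q: np.ndarray) -> np.ndarray:
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def matrix_to_quat(R: np.ndarray) -> np.ndarray:
    t = np.trace(R)
    if t > 0:
        w = np.sqrt(1.0 + t) / 2.0
        x = (R[2, 1] - R[1, 2]) / (4 * w)
        y = (R[0, 2] - R[2, 0]) / (4 * w)
        z = (R[1, 0] - R[0, 1]) / (4 * w)
    else:
        i = int(np.argmax(np.diag(R)))
        j, k = (i + 1) % 3, (i + 2) % 3
        s = np.sqrt(1.0 + R[i, i] - R[j, j] - R[k, k]) * 2.0
        qi = s / 4.0
        w = (R[k, j] - R[j, k]) / s
        qj = (R[j, i] + R[i, j]) / s
        qk = (R[k, i] + R[i, k]) / s
        vec = np.zeros(3)
        vec[i], vec[j], vec[k] = qi, qj, qk
        x, y, z = vec
    q = np.array([w, x, y, z])
    if q[0] < 0:
        q = -q
    return q / np.linalg.norm(q)


def rotation_angle_deg(q1: np.ndarray, q2: np.ndarray) -> float:
    """Rotation angle (degrees) between two unit quaternions."""
    d = min(abs(float(np.dot(q1, q2))), 1.0)
    return float(np.degrees(2.0 * np.arccos(d)))


@dataclass
class Pose:
    """Rigid pose: rotation about the structure centroid, then translation."""

    rotation: np.ndarray = field(default_factory=lambda: np.array([1.0, 0, 0, 0]))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, float)
        self.translation = np.asarray(self.translation, float)
        n = np.linalg.norm(self.rotation)
        if abs(n - 1.0) > 1e-6:
            raise ValueError("pose quaternion must be unit length")
        self.rotation = self.rotation / n

    def matrix(self) -> np.ndarray:
        return quat_to_matrix(self.rotation)

    def apply(self, coords: np.ndarray, center: np.ndarray) -> np.ndarray:
        """x -> R (x - c) + c + t."""
        R = self.matrix()
        return (np.asarray(coords) - center) @ R.T + center + self.translation

    def apply_to_structure(self, structure: AtomicStructure) -> AtomicStructure:
        return structure.transformed(self.matrix(), self.translation,
                                     center=structure.centroid())

    def inverse(self) -> "Pose":
        q_inv = self.rotation * np.array([1.0, -1, -1, -1])
        return Pose(rotation=q_inv,
                    translation=-quat_to_matrix(q_inv) @ self.translation)


@dataclass
class DockHit:
    pose: Pose
    cc: float
    normalized_cc: float
    cluster_size: int = 1


@dataclass
class DockResult:
    hits: list[DockHit]
    settings: dict = field(default_factory=dict)


def orientation_grid(angular_step: float) -> np.ndarray:
    """Deterministic near-uniform unit quaternions covering SO(3).

    Super-Fibonacci spiral on the quaternion hemisphere, with the point
    count chosen so the covering radius is about ``angular_step`` degrees.
    """
    if not 5.0 <= angular_step <= 60.0:
        raise ValueError("angular_step must lie in [5, 60] degrees")
    step_rad = np.radians(angular_step)
    n = max(60, int(np.ceil(_SO3_COVERING_K / step_rad**3)))
    i = np.arange(n, dtype=float) + 0.5
    s = i / n
    r = np.sqrt(s)
    big_r = np.sqrt(1.0 - s)
    alpha = 2.0 * np.pi * i / np.sqrt(2.0)
    beta = 2.0 * np.pi * i / 1.533751168755204288118041
    q = np.stack([r * np.sin(alpha), r * np.cos(alpha),
                  big_r * np.sin(beta), big_r * np.cos(beta)], axis=1)
    q[q[:, 0] < 0] *= -1.0  # canonical hemisphere
    return q


def _probe_arrays(probe: AtomicStructure):
    atoms = probe.heavy_atoms()
    if not atoms:
        raise EmptySelectionError("probe structure has no heavy atoms")
    coords = np.array([a.coord for a in atoms])
    weights = np.array([float(atomic_number(a.element)) for a in atoms])
    return coords, weights


def _rasterize(coords: np.ndarray, weights: np.ndarray, like: DensityMap,
               sigma: float) -> np.ndarray:
    values = np.zeros(like.values.shape)
    _splat_gaussians(values, like.origin, like.voxel_size, coords, weights, sigma)
    return values


def _shift_values(n: int) -> np.ndarray:
    """Signed circular shift for each FFT index."""
    s = np.arange(n)
    return np.where(s <= n // 2, s, s - n)


def exhaustive_search(density_map: DensityMap, probe: AtomicStructure,
                      resolution: float, angular_step: float = 20.0,
                      laplacian: bool = False, top_n: int = 10) -> DockResult:
    """Unbiased 6D rigid-body search of ``probe`` in ``density_map``.

    For every orientation on the deterministic grid, the probe is blurred to
    ``resolution`` and all in-bounds voxel translations are scored at once by
    FFT cross-correlation (full-map Pearson). The best translation per
    orientation is kept; hits are clustered (radii: 2 x angular_step in
    rotation, 1.5 x voxel in translation) and returned ranked by correlation,
    ties broken by enumeration order.
    """
    if density_map.values.std() == 0:
        raise DegenerateGeometryError("target map has zero variance")
    coords, weights = _probe_arrays(probe)
    extent = np.array(density_map.values.shape) * density_map.voxel_size
    probe_span = coords.max(axis=0) - coords.min(axis=0)
    if np.any(probe_span > extent):
        raise DegenerateGeometryError("probe is larger than the map extent")

    target = laplacian_filter(density_map) if laplacian else density_map
    a = target.values
    n_vox = a.size
    fa = np.fft.rfftn(a)
    s_a, s_aa = a.sum(), (a * a).sum()
    var_a = s_aa - s_a * s_a / n_vox

    centroid = coords.mean(axis=0)
    shape = np.array(density_map.values.shape)
    center_pos = density_map.origin + density_map.voxel_size * (shape - 1) / 2.0
    sigma = resolution * _FWHM_TO_SIGMA
    voxel = density_map.voxel_size

    shifts = [_shift_values(n) for n in shape]
    quats = orientation_grid(angular_step)
    raw_hits: list[tuple[float, Pose]] = []
    for q in quats:
        R = quat_to_matrix(q)
        rc = (coords - centroid) @ R.T + center_pos
        b = _rasterize(rc, weights, density_map, sigma)
        if laplacian:
            b = laplacian_filter(density_map.copy_with(b)).values
        s_b, s_bb = b.sum(), (b * b).sum()
        var_b = s_bb - s_b * s_b / n_vox
        if var_b <= 0:
            continue
        corr = np.fft.irfftn(fa * np.conj(np.fft.rfftn(b)), s=tuple(shape),
                             axes=(0, 1, 2))
        cc = (corr - s_a * s_b / n_vox) / np.sqrt(var_a * var_b)
        # mask shifts that would wrap the probe's effective support around
        # the grid (support = voxels above a tiny fraction of the maximum)
        thresh = 1e-8 * b.max()
        valid = np.ones(tuple(shape), dtype=bool)
        for ax in range(3):
            other = tuple(d for d in range(3) if d != ax)
            prof = np.where(b.max(axis=other) > thresh)[0]
            lo_i, hi_i = int(prof[0]), int(prof[-1])
            sv = shifts[ax]
            ok = (sv >= -lo_i) & (sv <= shape[ax] - 1 - hi_i)
            sl = [None, None, None]
            sl[ax] = slice(None)
            valid &= ok[tuple(sl)]
        if not valid.any():
            continue
        cc_masked = np.where(valid, cc, -np.inf)
        best = np.unravel_index(int(np.argmax(cc_masked)), tuple(shape))
        s_vec = np.array([shifts[ax][best[ax]] for ax in range(3)], float)
        t = center_pos - centroid + s_vec * voxel
        raw_hits.append((float(cc_masked[best]), Pose(rotation=q, translation=t)))

    if not raw_hits:
        raise DegenerateGeometryError("no valid placements found")
    order = sorted(range(len(raw_hits)), key=lambda i: -raw_hits[i][0])
    rot_radius = 2.0 * angular_step
    trans_radius = 1.5 * voxel
    reps: list[list] = []  # [cc, pose, size]
    for i in order:
        cc_i, pose_i = raw_hits[i]
        joined = False
        for rep in reps:
            if (rotation_angle_deg(pose_i.rotation, rep[1].rotation) <= rot_radius
                    and np.linalg.norm(pose_i.translation - rep[1].translation)
                    <= trans_radius):
                rep[2] += 1
                joined = True
                break
        if not joined:
            reps.append([cc_i, pose_i, 1])
    reps = reps[:top_n]
    cc_top = reps[0][0]
    hits = [DockHit(pose=p, cc=cc, normalized_cc=cc / cc_top if cc_top != 0 else 0.0,
                    cluster_size=size)
            for cc, p, size in reps]
    return DockResult(hits=hits, settings={
        "angular_step": angular_step, "laplacian": laplacian,
        "resolution": resolution, "n_orientations": len(quats)})


def _pose_cc(density_map: DensityMap, coords: np.ndarray, weights: np.ndarray,
             centroid: np.ndarray, pose: Pose, sigma: float,
             laplacian: bool = False) -> float:
    moved = (coords - centroid) @ pose.matrix().T + centroid + pose.translation
    lo = density_map.origin
    hi = density_map.origin + density_map.voxel_size * (
        np.array(density_map.values.shape) - 1)
    center = moved.mean(axis=0)
    if np.any(center < lo) or np.any(center > hi):
        return -np.inf
    b = _rasterize(moved, weights, density_map, sigma)
    target = density_map.values
    if laplacian:
        from .density import _LAPLACIAN_KERNEL  # local to avoid cycle noise
        from scipy import ndimage
        target = ndimage.convolve(target, _LAPLACIAN_KERNEL, mode="nearest")
        b = ndimage.convolve(b, _LAPLACIAN_KERNEL, mode="nearest")
    av = target.ravel() - target.mean()
    bv = b.ravel() - b.mean()
    denom = np.sqrt((av @ av) * (bv @ bv))
    if denom == 0:
        return -np.inf
    return float((av @ bv) / denom)


def refine_pose(density_map: DensityMap, probe: AtomicStructure, start: Pose,
                resolution: float, laplacian: bool = False):
    """Local derivative-free maximization of the correlation over 6 pose
    parameters. The returned correlation is never below the starting one;
    if the probe drifts out of map support a warning is issued and the best
    in-bounds pose is returned. Terminates when simplex steps fall below
    about 0.25 deg / 0.1 Å.
    """
    coords, weights = _probe_arrays(probe)
    centroid = coords.mean(axis=0)
    sigma = resolution * _FWHM_TO_SIGMA
    R_start = start.matrix()
    t_start = start.translation.copy()

    best = {"cc": _pose_cc(density_map, coords, weights, centroid, start,
                           sigma, laplacian),
            "pose": start}
    if not np.isfinite(best["cc"]):
        warnings.warn("starting pose places probe outside map support", stacklevel=2)
        best["cc"] = -1.0
    hit_boundary = False

    def params_to_pose(p):
        rotvec = np.radians(p[:3])
        angle = np.linalg.norm(rotvec)
        if angle < 1e-12:
            R_d = np.eye(3)
        else:
            k = rotvec / angle
            K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
            R_d = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * K @ K
        R_tot = R_d @ R_start
        return Pose(rotation=matrix_to_quat(R_tot), translation=t_start + p[3:])

    def objective(p):
        nonlocal hit_boundary
        pose = params_to_pose(p)
        cc = _pose_cc(density_map, coords, weights, centroid, pose, sigma, laplacian)
        if not np.isfinite(cc):
            hit_boundary = True
            return 2.0
        if cc > best["cc"]:
            best["cc"], best["pose"] = cc, pose
        return -cc

    minimize(objective, np.zeros(6), method="Nelder-Mead",
             options={"xatol": 0.1, "fatol": 1e-8, "maxiter": 800,
                      "initial_simplex": np.vstack([np.zeros(6),
                                                    np.eye(6) * 2.0])})
    if hit_boundary:
        warnings.warn("probe left map support during refinement; "
                      "best in-bounds pose returned", stacklevel=2)
    return best["pose"], best["cc"]


def compare_placements(density_map: DensityMap,
                       candidates: list[tuple[AtomicStructure, Pose]],
                       resolution: float):
    """Refine each candidate placement in place and rank by model-support
    masked correlation (descending). Returns [(candidate index, cc), ...]."""
    if len(candidates) < 2:
        if len(candidates) == 1:
            structure, pose = candidates[0]
            placed = pose.apply_to_structure(structure)
            sim = simulate_on_grid(placed, resolution, density_map)
            return [(0, cross_correlation(density_map, sim, "model_support"))]
        raise ValueError("compare_placements needs >= 1 candidate")
    scored = []
    for idx, (structure, pose) in enumerate(candidates):
        refined, _ = refine_pose(density_map, structure, pose, resolution)
        placed = refined.apply_to_structure(structure)
        sim = simulate_on_grid(placed, resolution, density_map)
        cc = cross_correlation(density_map, sim, "model_support")
        scored.append((idx, cc))
    return sorted(scored, key=lambda x: -x[1])
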