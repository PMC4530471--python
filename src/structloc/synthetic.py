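"""Synthetic data with known ground truth for every pipeline stage.

Every generator is a pure function of its arguments including the seed, so
regeneration is bit-identical. The generated conditions mirror the
experimental setups the pipeline targets: multi-helix toy domains blurred
into noisy density maps, acceptor-photobleach FRET panels from a known
acceptor coordinate, reporter-dye melt curves on a 25-95 °C grid with
0.5 °C steps, and one-site binding/dissociation series.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from .assays import BindingSeries, MeltCurve
from .density import DensityMap, simulate_map
from .docking import Pose
from .fret import FretMeasurement, distance_to_efficiency
from .structure import Atom, AtomicStructure, SSESegment, vdw_radius

# ideal backbone geometry (lengths Å, angles deg) and alpha-helix torsions
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_CA_CB = 1.458, 1.525, 1.329, 1.231, 1.521
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.8
_PHI, _PSI, _OMEGA = -57.0, -47.0, 180.0


@dataclass
class GroundTruth:
    """Generative parameters carried alongside every synthetic dataset."""

    seed: int
    generative_pose: Pose | None = None
    acceptor_coord: np.ndarray | None = None
    donor_coords: list | None = None
    melt_midpoints: list | None = None
    binding_params: dict | None = None
    extras: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        def enc(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, Pose):
                return {"rotation": o.rotation.tolist(),
                        "translation": o.translation.tolist()}
            return str(o)
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=enc)


def _place_nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                length: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom d given a-b-c with |cd|, angle(bcd), torsion(abcd)."""
    ang = np.radians(angle_deg)
    tor = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([-length * np.cos(ang),
                        length * np.sin(ang) * np.cos(tor),
                        length * np.sin(ang) * np.sin(tor)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _ideal_helix(n_res: int) -> list[tuple[str, np.ndarray]]:
    """Poly-alanine alpha-helix backbone (N, CA, C, O) + CB via ideal geometry."""
    atoms: list[tuple[str, np.ndarray]] = []
    N = np.array([0.0, 0.0, 0.0])
    CA = np.array([_B_N_CA, 0.0, 0.0])
    ang = np.radians(_A_N_CA_C)
    C = CA + _B_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    for i in range(n_res):
        if i > 0:
            # previous residue's atoms: N=[-5], CA=[-4]; C is still in hand
            N = _place_nerf(atoms[-5][1], atoms[-4][1], C, _B_C_N, _A_CA_C_N, _PSI)
            CA = _place_nerf(atoms[-4][1], C, N, _B_N_CA, _A_C_N_CA, _OMEGA)
            C = _place_nerf(C, N, CA, _B_CA_C, _A_N_CA_C, _PHI)
        atoms.append(("N", N.copy()))
        atoms.append(("CA", CA.copy()))
        atoms.append(("C", C.copy()))
        O = _place_nerf(N, CA, C, _B_C_O, _A_CA_C_O, _PSI + 180.0)
        atoms.append(("O", O))
        # CB from the local N/C/CA frame (standard ideal constants)
        bvec = CA - N
        cvec = C - CA
        avec = np.cross(bvec, cvec)
        CB = CA - 0.58273431 * avec + 0.56802827 * bvec - 0.54067466 * cvec
        atoms.append(("CB", CB))
    return atoms


def _align_to_z(coords: np.ndarray) -> np.ndarray:
    """Rotate so the principal axis of the point cloud lies along +z."""
    centered = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    axis = vt[0]
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, z)
    s = np.linalg.norm(v)
    c = float(np.dot(axis, z))
    if s < 1e-12:
        R = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        K = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R = np.eye(3) + K + K @ K * ((1 - c) / s**2)
    return centered @ R.T


def _hex_grid(n: int, spacing: float) -> list[np.ndarray]:
    """First n sites of a hexagonal packing in the xy plane."""
    sites = []
    row = 0
    while len(sites) < n:
        y = row * spacing * np.sqrt(3) / 2.0
        x0 = (row % 2) * spacing / 2.0
        for col in range(max(2, n)):
            sites.append(np.array([x0 + col * spacing, y, 0.0]))
            if len(sites) >= n:
                break
        row += 1
    return sites[:n]


def _random_rotation(rng: np.random.Generator, max_angle_deg: float) -> np.ndarray:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.radians(max_angle_deg) * rng.random()
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * K @ K


def make_toy_structure(n_helices: int = 3, helix_length: int = 20,
                       seed: int = 0) -> AtomicStructure:
    """Toy multi-domain structure: ideal poly-alanine helices on a hexagonal
    grid (10 Å spacing) with small seeded rigid jitter; SSE annotation
    attached. Chain A, residues numbered consecutively across helices."""
    if n_helices < 1:
        raise ValueError("n_helices must be >= 1")
    rng = np.random.default_rng(seed)
    template = _ideal_helix(helix_length)
    names = [n for n, _ in template]
    coords0 = _align_to_z(np.array([c for _, c in template]))
    sites = _hex_grid(n_helices, 10.0)
    atoms: list[Atom] = []
    sse: list[SSESegment] = []
    serial = 1
    for h in range(n_helices):
        R = _random_rotation(rng, 8.0)
        jitter = rng.uniform(-1.5, 1.5, size=3)
        coords = coords0 @ R.T + sites[h] + jitter
        res_offset = h * helix_length
        atom_idx = 0
        for i in range(helix_length):
            for _ in range(5):
                name = names[atom_idx]
                elem = name[0]
                atoms.append(Atom(
                    serial=serial, element=elem, vdw_radius=vdw_radius(elem),
                    coord=coords[atom_idx], chain_id="A",
                    residue_number=res_offset + i + 1, residue_name="ALA",
                    atom_name=name))
                serial += 1
                atom_idx += 1
        sse.append(SSESegment(kind="helix", chain_id="A",
                              start_residue=res_offset + 1,
                              end_residue=res_offset + helix_length,
                              label=f"H{h + 1}"))
    return AtomicStructure(atoms=atoms, sse_annotation=sse)


# Five donor sites mirroring the scale of the FKBP labelling positions:
# pairwise separations in the 20-60 Å band where a 59 Å Förster radius is
# informative.
DEFAULT_DONOR_SITES = {
    "D32": np.array([0.0, 0.0, 0.0]),
    "D44": np.array([28.0, 6.0, -4.0]),
    "D49": np.array([14.0, 26.0, 10.0]),
    "D85": np.array([-10.0, 18.0, -20.0]),
    "D97": np.array([6.0, -18.0, 20.0]),
}

# Default synthetic acceptor: 47-68 Å from every donor (0.8-1.16 x the
# 59 Å Förster radius), the regime a trilateration experiment is designed
# for — transfer efficiencies 0.3-0.8, where the E -> R conversion is
# well-conditioned and unaffected by clipping at E = 0 or 1.
DEFAULT_ACCEPTOR = np.array([-26.0, 23.0, 34.0])


def simulate_fret_dataset(donor_coords: list[np.ndarray], acceptor: np.ndarray,
                          forster_radius: float = 59.0,
                          noise_sd_efficiency: float = 0.05,
                          n_cells: int = 30, seed: int = 0,
                          site_names: list[str] | None = None):
    """Per-cell acceptor-photobleach measurements from a known acceptor.

    For each donor the true efficiency follows the Förster relation; each
    cell draws E + N(0, noise_sd) clipped to [0, 1] and is expressed as an
    intensity pair with f_post = 100 and f_pre = 100 (1 - E_cell).
    """
    if len(donor_coords) < 3:
        raise ValueError("need >= 3 donors")
    if noise_sd_efficiency < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    acceptor = np.asarray(acceptor, float)
    names = site_names or [f"D{i + 1}" for i in range(len(donor_coords))]
    measurements: list[FretMeasurement] = []
    for name, donor in zip(names, donor_coords):
        r = float(np.linalg.norm(np.asarray(donor, float) - acceptor))
        e_true = distance_to_efficiency(r, forster_radius)
        e_cells = np.clip(e_true + rng.normal(0.0, noise_sd_efficiency, n_cells),
                          0.0, 1.0)
        for e in e_cells:
            measurements.append(FretMeasurement(
                donor_site=name, f_prebleach=100.0 * (1.0 - e),
                f_postbleach=100.0, n_cells=1))
    truth = GroundTruth(seed=seed, acceptor_coord=acceptor,
                        donor_coords=[np.asarray(d, float) for d in donor_coords],
                        extras={"forster_radius": forster_radius,
                                "noise_sd_efficiency": noise_sd_efficiency,
                                "n_cells": n_cells,
                                "site_names": names})
    return measurements, truth


def simulate_noisy_map(structure: AtomicStructure, resolution: float = 6.0,
                       voxel: float = 1.5, snr: float = 4.0, seed: int = 0,
                       padding: float = 8.0):
    """Blurred map plus white Gaussian noise.

    Noise variance = (signal variance over model support) / snr, where the
    support is voxels above 10% of the clean maximum.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    clean = simulate_map(structure, resolution, voxel, padding=padding)
    support = clean.values > 0.1 * clean.values.max()
    sig_var = float(clean.values[support].var())
    rng = np.random.default_rng(seed)
    noisy = clean.values + rng.normal(0.0, np.sqrt(sig_var / snr),
                                      clean.values.shape)
    dmap = DensityMap(values=noisy, voxel_size=voxel, origin=clean.origin,
                      resolution_label=resolution)
    truth = GroundTruth(seed=seed, generative_pose=Pose(),
                        extras={"resolution": resolution, "snr": snr,
                                "signal_variance": sig_var})
    return dmap, truth


def simulate_melt_curve(midpoints, amplitudes=None, slopes=None,
                        noise_sd: float = 0.0, seed: int = 0):
    """Sum of logistic unfolding transitions on the 25-95 °C, 0.5 °C grid,
    plus a linear post-transition (aggregation) decay and Gaussian noise."""
    midpoints = list(midpoints)
    amplitudes = list(amplitudes) if amplitudes is not None else [1.0] * len(midpoints)
    slopes = list(slopes) if slopes is not None else [1.5] * len(midpoints)
    if not len(midpoints) == len(amplitudes) == len(slopes):
        raise ValueError("midpoints, amplitudes and slopes must have equal length")
    if any(s <= 0 for s in slopes):
        raise ValueError("slopes must be positive")
    temp = np.arange(25.0, 95.0 + 1e-9, 0.5)
    signal = np.full_like(temp, 0.05)  # dye baseline
    for m, a, s in zip(midpoints, amplitudes, slopes):
        signal = signal + a / (1.0 + np.exp(-(temp - m) / s))
    total_amp = sum(abs(a) for a in amplitudes)
    if total_amp > 0:
        t_aggr = max(midpoints) + 5.0 * max(slopes)
        signal = signal - 0.02 * total_amp * np.maximum(0.0, temp - t_aggr)
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        signal = signal + rng.normal(0.0, noise_sd * max(total_amp, 1e-9),
                                     temp.shape)
    curve = MeltCurve(temperatures=temp, fluorescence=signal)
    truth = GroundTruth(seed=seed, melt_midpoints=midpoints,
                        extras={"amplitudes": amplitudes, "slopes": slopes,
                                "noise_sd": noise_sd})
    return curve, truth


def simulate_binding(kd: float = 1.0, bmax: float = 100.0, koff: float = 0.1,
                     noise_sd: float = 0.0, seed: int = 0):
    """One-site saturation series (8 log-spaced concentrations, kd/30 to
    30 kd) and single-exponential dissociation series (12 time points, 0 to
    5/koff), with multiplicative Gaussian noise."""
    if kd <= 0 or bmax <= 0 or koff <= 0:
        raise ValueError("kd, bmax, koff must be positive")
    rng = np.random.default_rng(seed)
    conc = np.logspace(np.log10(kd / 30.0), np.log10(30.0 * kd), 8)
    sat_signal = bmax * conc / (kd + conc)
    times = np.linspace(0.0, 5.0 / koff, 12)
    dis_signal = bmax * np.exp(-koff * times)
    if noise_sd > 0:
        sat_signal = sat_signal * (1.0 + rng.normal(0.0, noise_sd, conc.shape))
        dis_signal = dis_signal * (1.0 + rng.normal(0.0, noise_sd, times.shape))
    saturation = BindingSeries(x=conc, signal=sat_signal)
    dissociation = BindingSeries(x=times, signal=dis_signal)
    truth = GroundTruth(seed=seed,
                        binding_params={"kd": kd, "bmax": bmax, "koff": koff,
                                        "noise_sd": noise_sd})
    return saturation, dissociation, truth
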