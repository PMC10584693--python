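"""Ground-truthed synthetic data for every pipeline stage.

Emulates the study's raw inputs without any external downloads:

* 3D two-channel stacks of single yeast cells — an ellipsoidal cell mask, a
  random-walk tubular mitochondrial network confined to it, and
  diffraction-limited nucleoid foci placed on the network, rendered with
  PSF blur and Poisson + Gaussian noise;
* qPCR plates (technical-replicate Cq values plus standard-dilution
  series) generated by inverting the standard-curve chemistry from known
  copy numbers;
* cell populations obeying a linear copies-versus-volume law with a fixed
  number of mtDNA copies per nucleoid.

Every generator takes a seed and is bit-deterministic; every output is
accompanied by its ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .image_pipeline import ImageStack
from .qpcr import MITO_GENES, NUCLEAR_GENES, StandardCurve, concentration_to_cq, ndna_per_cell

__all__ = [
    "DEFAULT_VOXEL_SIZE",
    "NoiseModel",
    "GroundTruth",
    "make_cell",
    "make_network",
    "place_nucleoids",
    "render",
    "simulate_qpcr",
    "simulate_population",
]

#: z step from the imaging protocol (0.35 µm); xy near Nyquist for the
#: 0.222 µm lateral resolution limit.
DEFAULT_VOXEL_SIZE: tuple[float, float, float] = (0.35, 0.1, 0.1)


@dataclass(frozen=True)
class NoiseModel:
    """Detection noise: Poisson shot noise at ``photon_scale`` photons per
    intensity unit (0 disables), additive Gaussian read noise, and a
    constant background offset."""

    photon_scale: float = 200.0
    read_noise_sd: float = 0.02
    offset: float = 0.1

    def __post_init__(self) -> None:
        if self.photon_scale < 0 or self.read_noise_sd < 0 or self.offset < 0:
            raise ValueError("noise parameters must be >= 0")

    def apply(self, clean: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        out = clean + self.offset
        if self.photon_scale > 0:
            out = rng.poisson(np.clip(out, 0, None) * self.photon_scale) / self.photon_scale
        if self.read_noise_sd > 0:
            out = out + rng.normal(0.0, self.read_noise_sd, size=out.shape)
        return out


@dataclass(frozen=True)
class GroundTruth:
    """Generation record attached to every rendered stack."""

    nucleoid_coords_um: np.ndarray  # (N, 3) physical (z, y, x)
    nucleoid_count: int
    network_mask: np.ndarray
    network_volume_um3: float
    seed: int
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.nucleoid_count != len(self.nucleoid_coords_um):
            raise ValueError("count must equal the number of coordinates")


# ---------------------------------------------------------------------------
# geometry


def make_cell(
    volume_fl: float,
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE,
    seed: int = 0,
    aspect: float = 1.15,
    margin_um: float = 0.6,
) -> tuple[np.ndarray, float]:
    """Ellipsoidal cell mask of ~volume_fl (1 fL = 1 µm³), within 5%.

    The ellipsoid is mildly prolate along y (axis ratio ``aspect``); the
    seed only perturbs the aspect slightly so that equal volumes do not
    produce voxel-identical cells.  Returns (mask, achieved volume in fL).
    """
    if volume_fl <= 0:
        raise ValueError("volume_fl must be > 0")
    vz, vy, vx = voxel_size
    voxvol = vz * vy * vx
    if volume_fl < voxvol:
        raise ValueError("target volume is below one voxel")
    rng = np.random.default_rng(seed)
    asp = aspect * (1.0 + 0.05 * rng.uniform(-1, 1))
    # semi-axes (rz, ry, rx) with ry = asp * r, rz = rx = r
    r = (volume_fl * 3.0 / (4.0 * math.pi * asp)) ** (1.0 / 3.0)
    radii = np.array([r, asp * r, r])
    shape = tuple(
        int(math.ceil(2 * (rad + margin_um) / vs))
        for rad, vs in zip(radii, voxel_size)
    )
    center = np.array([(s - 1) / 2.0 for s in shape])
    zz, yy, xx = np.indices(shape)
    coords = np.stack([zz * vz, yy * vy, xx * vx])
    center_um = center * np.array(voxel_size)

    def volume_of(scale: float) -> tuple[np.ndarray, float]:
        d2 = sum(
            ((coords[i] - center_um[i]) / (radii[i] * scale)) ** 2 for i in range(3)
        )
        m = d2 <= 1.0
        return m, float(m.sum()) * voxvol

    mask, vol = volume_of(1.0)
    # one refinement step corrects the voxelization bias
    if vol > 0 and abs(vol - volume_fl) / volume_fl > 0.01:
        mask, vol = volume_of((volume_fl / vol) ** (1.0 / 3.0))
    if vol == 0 or abs(vol - volume_fl) / volume_fl > 0.05:
        raise ValueError("could not voxelize the cell within 5% of target volume")
    return mask, vol


def make_network(
    cell_mask: np.ndarray,
    volume_fraction: float,
    tube_radius_um: float = 0.15,
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE,
    seed: int = 0,
    fragments: int = 1,
    step_um: float = 0.2,
    max_retries: int = 5,
) -> tuple[np.ndarray, np.ndarray]:
    """Random-walk tubular network confined to the cell mask.

    Walks a persistent random path (per fragment) through the region where
    a tube of ``tube_radius_um`` fits inside the cell, until the tube mask
    reaches ``volume_fraction`` of the cell volume (within 10%).

    Returns (centerline points (M, 3) in µm, boolean tube mask).
    """
    if not (0 < volume_fraction < 0.5):
        raise ValueError("volume_fraction must be in (0, 0.5)")
    cell_mask = np.asarray(cell_mask, dtype=bool)
    voxvol = float(np.prod(voxel_size))
    target_um3 = cell_mask.sum() * voxvol * volume_fraction

    # admissible region for centerlines: deeper inside than the tube radius
    depth = ndimage.distance_transform_edt(cell_mask, sampling=voxel_size)
    interior = depth > tube_radius_um
    if not interior.any():
        raise ValueError("tube radius too large for this cell")
    interior_idx = np.array(np.nonzero(interior)).T  # (K, 3) voxel coords
    vs = np.array(voxel_size)

    # rough walk length needed (volume / pi r^2); grown in chunks with the
    # achieved voxel volume re-measured after each, so voxelization bias
    # cannot push the result outside the tolerance
    est_len_um = target_um3 / (math.pi * tube_radius_um**2)
    chunk_steps = max(int(est_len_um / step_um / 25), 2)
    shape = np.array(cell_mask.shape)

    for attempt in range(max_retries):
        rng = np.random.default_rng(seed + 104729 * attempt)
        starts = interior_idx[
            rng.choice(len(interior_idx), size=fragments, replace=False)
        ] * vs
        pos = [s.astype(float) for s in starts]
        direction = [rng.normal(size=3) for _ in range(fragments)]
        direction = [d / np.linalg.norm(d) for d in direction]
        pts: list[np.ndarray] = [p.copy() for p in pos]
        mask = None
        for _ in range(200):  # chunk budget
            for f in range(fragments):
                for _ in range(chunk_steps):
                    turn = rng.normal(scale=0.6, size=3)
                    d = direction[f] + turn
                    d /= np.linalg.norm(d)
                    cand = pos[f] + d * step_um
                    ci = np.round(cand / vs).astype(int)
                    if np.all(ci >= 0) and np.all(ci < shape) and interior[tuple(ci)]:
                        pos[f] = cand
                        direction[f] = d
                    else:  # bounce: pick a fresh direction
                        direction[f] = rng.normal(size=3)
                        direction[f] /= np.linalg.norm(direction[f])
                    pts.append(pos[f].copy())
            mask = _tube_mask(np.array(pts), cell_mask.shape, tube_radius_um, voxel_size)
            if mask.sum() * voxvol >= 0.95 * target_um3:
                break
        vol = mask.sum() * voxvol
        n_comp = ndimage.label(mask, structure=np.ones((3, 3, 3), int))[1]
        if abs(vol - target_um3) / target_um3 <= 0.10 and n_comp == fragments:
            return np.array(pts), mask
    raise ValueError(
        "could not build a network matching the volume/fragment targets; "
        "adjust tube_radius_um or volume_fraction"
    )


def _tube_mask(
    centerline_um: np.ndarray,
    shape: tuple[int, ...],
    radius_um: float,
    voxel_size: tuple[float, float, float],
) -> np.ndarray:
    """Voxels within radius_um (physical) of any centerline point."""
    seeds = np.zeros(shape, dtype=bool)
    idx = np.round(centerline_um / np.array(voxel_size)).astype(int)
    idx = np.clip(idx, 0, np.array(shape) - 1)
    seeds[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    dist = ndimage.distance_transform_edt(~seeds, sampling=voxel_size)
    return dist <= radius_um


def place_nucleoids(
    centerline_um: np.ndarray,
    count: int,
    min_separation_um: float,
    seed: int = 0,
    max_retries: int = 200,
    z_compression: float = 1.0,
) -> np.ndarray:
    """``count`` points on the centerline, pairwise >= min_separation_um apart.

    ``z_compression`` divides axial offsets before taking the Euclidean
    norm, turning the exclusion zone into a spheroid: with z_compression =
    r_z / r_xy and min_separation_um = 2 * r_xy, pairs are separated by
    twice the optical resolution in every direction (axial resolution being
    r_z / r_xy times worse than lateral).
    """
    if count < 0:
        raise ValueError("count must be >= 0")
    if count == 0:
        return np.zeros((0, 3))
    pts = np.asarray(centerline_um, dtype=float)
    scale = np.array([1.0 / z_compression, 1.0, 1.0])
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        order = rng.permutation(len(pts))
        chosen: list[np.ndarray] = []
        for i in order:
            p = pts[i]
            if all(
                np.linalg.norm((p - q) * scale) >= min_separation_um for q in chosen
            ):
                chosen.append(p)
                if len(chosen) == count:
                    return np.array(chosen)
    raise ValueError(
        f"cannot place {count} nucleoids at separation {min_separation_um} µm "
        "on this network"
    )


# ---------------------------------------------------------------------------
# rendering


def render(
    network_mask: np.ndarray,
    nucleoid_coords_um: np.ndarray,
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE,
    psf_sigma_um: tuple[float, float, float] = (0.5, 0.09, 0.09),
    noise: NoiseModel = NoiseModel(),
    spot_amplitude: float = 2.0,
    mito_amplitude: float = 1.0,
    leak: float = 0.3,
    seed: int = 0,
) -> tuple[ImageStack, ImageStack, GroundTruth]:
    """Render the two channels from a network mask and true spot positions.

    mito channel = mito_amplitude * network ⊛ PSF + noise.
    nucleoid channel = leak * mito_amplitude * network ⊛ PSF
                       + spots (Gaussian, s.d. = PSF sigma, at the exact µm
                         coordinates) + noise.

    The network leak into the nucleoid channel mimics unbound reporter in
    the matrix — it is what the final Welch validation exists to reject.
    """
    if spot_amplitude <= 0 or mito_amplitude <= 0:
        raise ValueError("amplitudes must be > 0")
    if any(s <= 0 for s in psf_sigma_um):
        raise ValueError("psf sigma must be > 0")
    network_mask = np.asarray(network_mask, dtype=bool)
    coords = np.asarray(nucleoid_coords_um, dtype=float).reshape(-1, 3)
    rng = np.random.default_rng(seed)
    vs = np.array(voxel_size)
    sigma_vox = np.array(psf_sigma_um) / vs

    net = ndimage.gaussian_filter(network_mask.astype(float), sigma=sigma_vox)
    spots = np.zeros(network_mask.shape)
    for c in coords:
        _add_gaussian_spot(spots, c, psf_sigma_um, voxel_size, spot_amplitude)

    mito_clean = mito_amplitude * net
    nuc_clean = leak * mito_amplitude * net + spots

    mito = NoiseModel.apply(noise, mito_clean, rng)
    nuc = NoiseModel.apply(noise, nuc_clean, rng)

    truth = GroundTruth(
        nucleoid_coords_um=coords,
        nucleoid_count=len(coords),
        network_mask=network_mask,
        network_volume_um3=float(network_mask.sum() * np.prod(vs)),
        seed=seed,
        params={
            "psf_sigma_um": tuple(psf_sigma_um),
            "spot_amplitude": spot_amplitude,
            "mito_amplitude": mito_amplitude,
            "leak": leak,
            "noise": noise.__dict__,
        },
    )
    return (
        ImageStack(nuc, tuple(voxel_size)),
        ImageStack(mito, tuple(voxel_size)),
        truth,
    )


def _add_gaussian_spot(
    img: np.ndarray,
    center_um: np.ndarray,
    sigma_um: tuple[float, float, float],
    voxel_size: tuple[float, float, float],
    amplitude: float,
    extent_sigmas: float = 4.0,
) -> None:
    """Accumulate an anisotropic Gaussian at an exact physical position."""
    vs = np.array(voxel_size)
    sig = np.array(sigma_um)
    c_vox = center_um / vs
    lo = np.maximum(np.floor(c_vox - extent_sigmas * sig / vs).astype(int), 0)
    hi = np.minimum(
        np.ceil(c_vox + extent_sigmas * sig / vs).astype(int) + 1,
        np.array(img.shape),
    )
    if np.any(lo >= hi):
        return
    grids = np.meshgrid(
        *[np.arange(l, h) for l, h in zip(lo, hi)], indexing="ij"
    )
    d2 = sum(
        ((grids[i] * vs[i] - center_um[i]) / sig[i]) ** 2 for i in range(3)
    )
    img[tuple(slice(l, h) for l, h in zip(lo, hi))] += amplitude * np.exp(-0.5 * d2)


def synthetic_cell_stack(
    seed: int,
    volume_fl: float | None = None,
    n_nucleoids: int | None = None,
    network_fraction: float = 0.10,
    tube_radius_um: float = 0.15,
    nucleoid_density_per_fl: float = 0.45,
    r_xy_um: float = 0.222,
    r_z_um: float = 1.0,
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE,
    **render_kwargs,
) -> tuple[ImageStack, ImageStack, np.ndarray, GroundTruth]:
    """One complete synthetic cell: both channels, cell mask and truth.

    Defaults emulate the study conditions: cells drawn from the engineered
    volume range (~35-95 fL unless ``volume_fl`` is given), a network
    occupying ~10% of the cell, and nucleoids at ~0.45 per fL (about 20 in
    a 50 fL cell), placed at twice the optical resolution apart — lateral
    separation >= 2*r_xy or the axially rescaled equivalent.

    Returns (nucleoid channel, mito channel, cell mask, ground truth).
    """
    rng = np.random.default_rng(seed)
    if volume_fl is None:
        volume_fl = float(rng.uniform(35.0, 95.0))
    if n_nucleoids is None:
        n_nucleoids = int(round(nucleoid_density_per_fl * volume_fl))
    cell_mask, achieved = make_cell(volume_fl, voxel_size, seed=seed)
    centerline, network = make_network(
        cell_mask, network_fraction, tube_radius_um, voxel_size, seed=seed
    )
    coords = place_nucleoids(
        centerline,
        n_nucleoids,
        min_separation_um=2.0 * r_xy_um,
        seed=seed,
        z_compression=r_z_um / r_xy_um,
    )
    nuc, mito, truth = render(
        network, coords, voxel_size=voxel_size, seed=seed, **render_kwargs
    )
    truth.params["cell_volume_fl"] = achieved
    return nuc, mito, cell_mask, truth


# ---------------------------------------------------------------------------
# qPCR and population simulators


def simulate_qpcr(
    mt_per_cell: np.ndarray,
    volumes_fl: np.ndarray,
    budding_index_pct: np.ndarray,
    ploidy: str = "haploid",
    curves: dict[str, StandardCurve] | None = None,
    cq_noise_sd: float = 0.1,
    replicates: int = 3,
    base_nuclear_conc: float = 0.01,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict]:
    """qPCR plate + standards + population tables from known copy numbers.

    Per-gene template concentrations are proportional to genome copies:
    nuclear genes at ``base_nuclear_conc`` pg/µL, mitochondrial genes at
    that times the true copies-per-nDNA ratio (the absolute scale cancels
    in the ratio, as in the real assay).  Cq values come from inverting
    each gene's standard curve plus Gaussian noise.

    Returns (plate, standards, populations, truth).
    """
    mt_per_cell = np.atleast_1d(np.asarray(mt_per_cell, dtype=float))
    volumes_fl = np.atleast_1d(np.asarray(volumes_fl, dtype=float))
    budding = np.atleast_1d(np.asarray(budding_index_pct, dtype=float))
    if not (len(mt_per_cell) == len(volumes_fl) == len(budding)):
        raise ValueError("per-sample arrays must have equal length")
    rng = np.random.default_rng(seed)
    if curves is None:
        curves = {
            g: StandardCurve(g, slope=-3.45 + 0.05 * i, intercept=20.0 + 0.7 * i)
            for i, g in enumerate(NUCLEAR_GENES + MITO_GENES)
        }

    # standard-dilution series 1e-4 .. 1 pg/µL, one Cq per point per gene
    std_conc = 10.0 ** np.arange(-4.0, 0.5, 1.0)
    std_rows = [
        {
            "gene": g,
            "concentration_pg_per_ul": c,
            "cq": concentration_to_cq(c, curves[g]) + rng.normal(0, cq_noise_sd / 3),
        }
        for g in curves
        for c in std_conc
    ]

    plate_rows, pop_rows = [], []
    for i, (mtc, vol, bud) in enumerate(zip(mt_per_cell, volumes_fl, budding)):
        sample = f"S{i:03d}"
        npc = ndna_per_cell(bud, ploidy)
        ratio = mtc / npc
        for g in NUCLEAR_GENES + MITO_GENES:
            conc = base_nuclear_conc * (ratio if g in MITO_GENES else 1.0)
            true_cq = concentration_to_cq(conc, curves[g])
            for r in range(replicates):
                plate_rows.append(
                    {
                        "sample": sample,
                        "gene": g,
                        "replicate": r,
                        "cq": true_cq + rng.normal(0, cq_noise_sd),
                    }
                )
        pop_rows.append(
            {
                "sample": sample,
                "mean_volume_fl": vol,
                "budding_index_pct": bud,
                "ploidy": ploidy,
            }
        )
    truth = {
        "mt_per_cell": mt_per_cell,
        "mt_per_ndna": mt_per_cell / np.array([ndna_per_cell(b, ploidy) for b in budding]),
        "curves": curves,
        "seed": seed,
    }
    return (
        pd.DataFrame(plate_rows),
        pd.DataFrame(std_rows),
        pd.DataFrame(pop_rows),
        truth,
    )


def simulate_population(
    n_cells: int,
    mean_volume_fl: float = 60.0,
    volume_cv: float = 0.3,
    copies_per_fl: float = 0.4,
    copies_per_nucleoid: float = 2.0,
    observation_cv: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Per-cell table obeying copies = copies_per_fl * volume.

    Volumes are lognormal (CV ~0.3, emulating the >4-fold engineered volume
    range); nucleoid counts are copies / copies_per_nucleoid; optional
    multiplicative Gaussian observation noise on both measurements.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log(1.0 + volume_cv**2))
    mu = math.log(mean_volume_fl) - 0.5 * sigma**2
    volumes = rng.lognormal(mu, sigma, size=n_cells)
    copies = copies_per_fl * volumes
    nucleoids = copies / copies_per_nucleoid
    if observation_cv > 0:
        copies = copies * (1.0 + rng.normal(0, observation_cv, n_cells))
        nucleoids = nucleoids * (1.0 + rng.normal(0, observation_cv, n_cells))
    table = pd.DataFrame(
        {"volume_fl": volumes, "copies_per_cell": copies, "nucleoids_per_cell": nucleoids}
    )
    truth = {
        "copies_per_fl": copies_per_fl,
        "copies_per_nucleoid": copies_per_nucleoid,
        "mean_volume_fl": mean_volume_fl,
        "volume_cv": volume_cv,
        "seed": seed,
    }
    return table, truth
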