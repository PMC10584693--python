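"""3D nucleoid counting and mitochondrial-network segmentation.

Per-cell analysis of two-channel confocal z-stacks (a nucleoid channel with
diffraction-limited mtDNA foci and a mitochondrial-matrix channel showing
the tubular network), on anisotropic voxel grids.  The stages are:

1. Gaussian smoothing of both channels (small sigma, in voxels).
2. Network segmentation of the mitochondria channel by Li auto-thresholding;
   the network volume is the voxel count of that mask.
3. Normalization of the mitochondria channel by the median in-network
   intensity.
4. 3D local-maxima detection in the nucleoid channel (candidate foci).
5. Intensity filtering of candidates by a Li threshold on the nucleoid
   channel.
6. Deduplication of candidates closer than the optical resolution: within a
   spheroid of lateral radius 0.61*lambda/NA and a fixed axial radius, only
   the brightest peak survives.
7. Iterative validation: a peak is a real nucleoid only if its nucleoid-
   channel intensity is significantly higher than the mitochondria signal
   over the same voxels (one Welch t-test per peak, repeated until the
   retained count stabilises, since each discard changes the background
   normalization).

Counting is deliberately conservative: every stage only removes peaks.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage, stats
from skimage.filters import threshold_li

__all__ = [
    "ImageStack",
    "PipelineConfig",
    "ResolutionSpheroid",
    "PeakSet",
    "NetworkSegmentation",
    "CellResult",
    "smooth",
    "li_threshold",
    "segment_network",
    "normalize_by_median",
    "detect_local_maxima",
    "filter_peaks_by_intensity",
    "resolution_spheroid",
    "dedup_peaks",
    "iterative_welch_filter",
    "analyze_cell",
]


@dataclass(frozen=True)
class ImageStack:
    """A 3D intensity grid with anisotropic voxel size.

    voxels : (nz, ny, nx) float array, arbitrary intensity units.
    voxel_size : (z, y, x) voxel edge lengths in micrometres.
    """

    voxels: np.ndarray
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels, dtype=float)
        if v.ndim != 3 or v.size == 0:
            raise ValueError("voxels must be a non-empty 3D array")
        if not np.all(np.isfinite(v)):
            raise ValueError("voxel intensities must be finite")
        if len(self.voxel_size) != 3 or any(s <= 0 for s in self.voxel_size):
            raise ValueError("voxel_size must be three positive lengths (z, y, x)")
        object.__setattr__(self, "voxels", v)
        object.__setattr__(self, "voxel_size", tuple(float(s) for s in self.voxel_size))

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.voxel_size))

    def with_voxels(self, voxels: np.ndarray) -> "ImageStack":
        return ImageStack(voxels, self.voxel_size)


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable parameters of the nucleoid-counting pipeline.

    sigma : Gaussian prefilter s.d. in voxels (isotropic in voxel index
        space, i.e. anisotropic in physical space, matching the smoothing
        the segmentation is calibrated to).
    na / lambda_nm : objective numerical aperture and emission wavelength,
        which set the lateral deduplication radius 0.61*lambda/NA.
    rz_um : axial deduplication radius in micrometres (optical sectioning is
        far worse than the lateral limit, so this is set independently).
    p_threshold : Welch-test p-value cut-off for step 7.
    max_iter : safety cap on the step-7 iteration.
    one_sided_welch : if True, halve the two-sided p before comparing with
        p_threshold (the discard rule already requires t > 0 either way).
    min_welch_voxels : smallest per-group sample size for which the t-test
        is attempted; peaks with fewer in-network voxels are discarded.
    """

    sigma: float = 0.75
    na: float = 1.4
    lambda_nm: float = 509.0
    rz_um: float = 1.0
    p_threshold: float = 0.025
    max_iter: int = 100
    one_sided_welch: bool = False
    min_welch_voxels: int = 3

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if not (0 < self.p_threshold < 1):
            raise ValueError("p_threshold must be in (0, 1)")
        if self.na <= 0 or self.lambda_nm <= 0 or self.rz_um <= 0:
            raise ValueError("na, lambda_nm and rz_um must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")

    @property
    def spheroid(self) -> "ResolutionSpheroid":
        return resolution_spheroid(self.na, self.lambda_nm, self.rz_um)


@dataclass(frozen=True)
class ResolutionSpheroid:
    """Resolution-limited volume: lateral radius r_xy, axial radius r_z (µm)."""

    r_xy: float
    r_z: float

    def __post_init__(self) -> None:
        if self.r_xy <= 0 or self.r_z <= 0:
            raise ValueError("spheroid radii must be > 0")

    def contains(self, dz_um: float, dy_um: float, dx_um: float) -> bool:
        """Whether an offset (µm) lies within the spheroid (boundary inclusive)."""
        return (
            (dx_um * dx_um + dy_um * dy_um) / (self.r_xy * self.r_xy)
            + (dz_um * dz_um) / (self.r_z * self.r_z)
        ) <= 1.0


@dataclass(frozen=True)
class PeakSet:
    """Candidate or accepted nucleoid positions.

    coords : (N, 3) int voxel indices (z, y, x).
    intensities : (N,) intensity at each peak.
    """

    coords: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        c = np.atleast_2d(np.asarray(self.coords, dtype=int))
        if c.size == 0:
            c = c.reshape(0, 3)
        inten = np.atleast_1d(np.asarray(self.intensities, dtype=float))
        if c.shape[0] != inten.shape[0] or c.shape[1] != 3:
            raise ValueError("coords must be (N, 3) and intensities (N,)")
        object.__setattr__(self, "coords", c)
        object.__setattr__(self, "intensities", inten)

    def __len__(self) -> int:
        return self.coords.shape[0]

    @classmethod
    def empty(cls) -> "PeakSet":
        return cls(np.zeros((0, 3), dtype=int), np.zeros(0))

    def select(self, keep: np.ndarray) -> "PeakSet":
        return PeakSet(self.coords[keep], self.intensities[keep])


@dataclass(frozen=True)
class NetworkSegmentation:
    """Binary mitochondrial-network mask with volume and fragment count."""

    mask: np.ndarray
    volume_voxels: int
    volume_um3: float
    fragments: int

    @classmethod
    def from_mask(cls, mask: np.ndarray, voxel_volume_um3: float) -> "NetworkSegmentation":
        mask = np.asarray(mask, dtype=bool)
        n = int(mask.sum())
        # 26-connectivity for tubes that run diagonally through the grid
        _, fragments = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=int))
        return cls(mask, n, n * voxel_volume_um3, int(fragments))


@dataclass(frozen=True)
class CellResult:
    """Per-cell pipeline output."""

    cell_id: int
    nucleoid_count: int
    network_volume_voxels: int
    network_volume_um3: float
    fragments: int
    peaks: PeakSet = field(repr=False, default_factory=PeakSet.empty)
    stage_counts: dict = field(repr=False, default_factory=dict)


# ---------------------------------------------------------------------------
# stages


def smooth(stack: ImageStack, sigma: float) -> ImageStack:
    """Stage 1: 3D Gaussian filter with s.d. ``sigma`` voxels on every axis."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    return stack.with_voxels(ndimage.gaussian_filter(stack.voxels, sigma=sigma))


def li_threshold(values: np.ndarray, tolerance: float | None = None) -> float:
    """Li cross-entropy threshold of an intensity sample.

    ``tolerance`` is the fixed-point stopping tolerance (default: half the
    smallest intensity gap).  Raises on a constant sample, for which no
    threshold is defined.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size < 2 or np.ptp(values) == 0:
        raise ValueError("Li threshold undefined for a constant sample")
    return float(threshold_li(values, tolerance=tolerance))


def segment_network(mito: ImageStack, cfg: PipelineConfig | None = None,
                    within: np.ndarray | None = None) -> NetworkSegmentation:
    """Stage 2: Li-threshold the (smoothed) mitochondria channel.

    ``within`` optionally restricts both the threshold computation and the
    output mask to a cell mask.  A constant signal (e.g. an empty channel)
    yields an empty segmentation with a warning rather than an error, so
    that cells without signal flow through the pipeline.
    """
    region = mito.voxels if within is None else mito.voxels[within]
    try:
        thr = li_threshold(region)
    except ValueError:
        warnings.warn("constant mitochondria signal; returning empty network mask")
        return NetworkSegmentation.from_mask(
            np.zeros(mito.voxels.shape, dtype=bool), mito.voxel_volume_um3
        )
    mask = mito.voxels >= thr
    if within is not None:
        mask &= within
    return NetworkSegmentation.from_mask(mask, mito.voxel_volume_um3)


def normalize_by_median(stack: ImageStack, mask: np.ndarray) -> ImageStack:
    """Stage 3: divide by the median intensity over ``mask`` voxels."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("cannot normalize by an empty mask")
    med = float(np.median(stack.voxels[mask]))
    if med == 0:
        raise ValueError("in-mask median is zero; cannot normalize")
    return stack.with_voxels(stack.voxels / med)


def detect_local_maxima(nucleoid: ImageStack, within: np.ndarray | None = None) -> PeakSet:
    """Stage 4: all 26-connectivity local maxima of the nucleoid channel.

    A voxel qualifies if it is >= every neighbour in its 3x3x3 window;
    plateaus (connected equal-valued maxima) contribute one representative,
    the lexicographically smallest (z, y, x).  ``within`` restricts the
    returned peaks to a cell mask.
    """
    v = nucleoid.voxels
    flat = ndimage.maximum_filter(v, size=3, mode="reflect") == v
    if within is not None:
        flat &= np.asarray(within, dtype=bool)
    if not flat.any():
        return PeakSet.empty()
    # Adjacent flagged voxels necessarily share a value, so plain connected
    # components group exactly the plateaus; keep the lexicographically
    # smallest (z, y, x) voxel of each.
    labels, n_lab = ndimage.label(flat, structure=np.ones((3, 3, 3), dtype=int))
    zz, yy, xx = np.nonzero(flat)
    lab = labels[zz, yy, xx]
    order = np.lexsort((xx, yy, zz))  # ascending (z, y, x)
    seen = np.zeros(n_lab + 1, dtype=bool)
    out = []
    for o in order:
        l = lab[o]
        if not seen[l]:
            seen[l] = True
            out.append((zz[o], yy[o], xx[o]))
    coords = np.array(out, dtype=int)
    return PeakSet(coords, v[coords[:, 0], coords[:, 1], coords[:, 2]])


def filter_peaks_by_intensity(
    peaks: PeakSet, nucleoid: ImageStack, within: np.ndarray | None = None
) -> PeakSet:
    """Stage 5: drop peaks below a Li threshold on the nucleoid channel."""
    if len(peaks) == 0:
        return peaks
    region = nucleoid.voxels if within is None else nucleoid.voxels[within]
    thr = li_threshold(region)
    return peaks.select(peaks.intensities >= thr)


def resolution_spheroid(na: float, lambda_nm: float, rz_um: float) -> ResolutionSpheroid:
    """Lateral resolution radius 0.61*lambda/NA (µm) with a fixed axial radius.

    At NA 1.4 and 509 nm emission this gives r_xy = 0.222 µm.
    """
    if na <= 0 or lambda_nm <= 0 or rz_um <= 0:
        raise ValueError("na, lambda_nm and rz_um must be > 0")
    r_xy_um = 0.61 * lambda_nm / na / 1000.0
    return ResolutionSpheroid(r_xy=r_xy_um, r_z=rz_um)


def dedup_peaks(
    peaks: PeakSet, sph: ResolutionSpheroid, voxel_size: tuple[float, float, float]
) -> PeakSet:
    """Stage 6: among peaks closer than the resolution limit keep the brightest.

    Greedy in descending intensity (ties broken by lexicographic coordinate
    order): a peak is accepted iff no already-accepted peak lies within the
    spheroid centred on it, with physical distances from the voxel size.
    """
    n = len(peaks)
    if n <= 1:
        return peaks
    vz, vy, vx = voxel_size
    c = peaks.coords.astype(float)
    phys = np.column_stack((c[:, 0] * vz, c[:, 1] * vy, c[:, 2] * vx))
    order = np.lexsort(
        (peaks.coords[:, 2], peaks.coords[:, 1], peaks.coords[:, 0], -peaks.intensities)
    )
    accepted: list[int] = []
    r_xy2 = sph.r_xy**2
    r_z2 = sph.r_z**2
    for i in order:
        ok = True
        for j in accepted:
            dz, dy, dx = phys[i] - phys[j]
            if (dx * dx + dy * dy) / r_xy2 + (dz * dz) / r_z2 <= 1.0:
                ok = False
                break
        if ok:
            accepted.append(i)
    keep = np.sort(np.array(accepted, dtype=int))
    return peaks.select(keep)


def _spheroid_voxel_indices(
    shape: tuple[int, ...],
    center: np.ndarray,
    sph: ResolutionSpheroid,
    voxel_size: tuple[float, float, float],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Indices of grid voxels inside the spheroid centred at ``center`` (voxel coords)."""
    vz, vy, vx = voxel_size
    ez = int(math.floor(sph.r_z / vz))
    ey = int(math.floor(sph.r_xy / vy))
    ex = int(math.floor(sph.r_xy / vx))
    z0, y0, x0 = (int(c) for c in center)
    zs = np.arange(max(z0 - ez, 0), min(z0 + ez + 1, shape[0]))
    ys = np.arange(max(y0 - ey, 0), min(y0 + ey + 1, shape[1]))
    xs = np.arange(max(x0 - ex, 0), min(x0 + ex + 1, shape[2]))
    zz, yy, xx = np.meshgrid(zs, ys, xs, indexing="ij")
    inside = (
        (((xx - x0) * vx) ** 2 + ((yy - y0) * vy) ** 2) / sph.r_xy**2
        + (((zz - z0) * vz) ** 2) / sph.r_z**2
    ) <= 1.0
    return zz[inside], yy[inside], xx[inside]


def iterative_welch_filter(
    peaks: PeakSet,
    nucleoid: ImageStack,
    mito_norm: ImageStack,
    mask: np.ndarray,
    sph: ResolutionSpheroid,
    cfg: PipelineConfig,
) -> PeakSet:
    """Stage 7: iteratively validate peaks against the mitochondria signal.

    Each pass (a) classifies in-network voxels as inside/outside the
    spheroids of the surviving peaks, (b) normalizes the nucleoid channel by
    the mean intensity over the outside voxels, (c) Welch-tests, per peak,
    the normalized nucleoid intensities against the median-normalized
    mitochondria intensities over that peak's in-network spheroid voxels,
    discarding the peak if p > p_threshold or t <= 0, and (d) repeats until
    the retained count stops changing.  The count is non-increasing, so the
    loop terminates.
    """
    mask = np.asarray(mask, dtype=bool)
    if len(peaks) == 0:
        return peaks
    if not mask.any():
        raise ValueError("network mask is empty")
    current = peaks
    shape = nucleoid.voxels.shape
    for _ in range(cfg.max_iter):
        if len(current) == 0:
            break
        inside = np.zeros(shape, dtype=bool)
        per_peak_vox = []
        for k in range(len(current)):
            zz, yy, xx = _spheroid_voxel_indices(
                shape, current.coords[k], sph, nucleoid.voxel_size
            )
            sel = mask[zz, yy, xx]
            per_peak_vox.append((zz[sel], yy[sel], xx[sel]))
            inside[zz[sel], yy[sel], xx[sel]] = True
        outside = mask & ~inside
        if not outside.any():
            raise ValueError(
                "no in-network voxels outside nucleoids; cannot normalize background"
            )
        bg = float(nucleoid.voxels[outside].mean())
        if bg <= 0:
            raise ValueError("non-positive background mean in nucleoid channel")
        nuc_norm = nucleoid.voxels / bg
        keep = np.ones(len(current), dtype=bool)
        for k, (zz, yy, xx) in enumerate(per_peak_vox):
            if zz.size < cfg.min_welch_voxels:
                warnings.warn(
                    f"peak {k}: only {zz.size} in-network voxels; discarded"
                )
                keep[k] = False
                continue
            a = nuc_norm[zz, yy, xx]
            b = mito_norm.voxels[zz, yy, xx]
            if np.ptp(a) == 0 and np.ptp(b) == 0:
                keep[k] = a.mean() > b.mean()  # zero variance: degenerate test
                continue
            t, p = stats.ttest_ind(a, b, equal_var=False)
            if cfg.one_sided_welch:
                p = p / 2.0
            keep[k] = (t > 0) and (p <= cfg.p_threshold)
        retained = current.select(keep)
        if len(retained) == len(current):
            return retained
        current = retained
    return current


def analyze_cell(
    nucleoid: ImageStack,
    mito: ImageStack,
    cell_mask: np.ndarray,
    cfg: PipelineConfig | None = None,
    cell_id: int = 0,
) -> CellResult:
    """Run stages 1-7 for one cell and return counts and network volume.

    All thresholds and statistics are computed over the cell mask only, so
    cells in a field of view are analysed independently.  A cell without
    mitochondrial signal yields an empty network and zero nucleoids.
    """
    cfg = cfg or PipelineConfig()
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if nucleoid.voxels.shape != mito.voxels.shape:
        raise ValueError("channel shapes differ")
    if cell_mask.shape != mito.voxels.shape:
        raise ValueError("cell mask shape differs from the image")
    if not cell_mask.any():
        raise ValueError("empty cell mask")

    nuc_s = smooth(nucleoid, cfg.sigma)
    mito_s = smooth(mito, cfg.sigma)

    seg = segment_network(mito_s, cfg, within=cell_mask)
    stage_counts: dict[str, int] = {}
    if seg.volume_voxels == 0:
        return CellResult(cell_id, 0, 0, 0.0, 0, PeakSet.empty(), {"candidates": 0})

    mito_norm = normalize_by_median(mito_s, seg.mask)

    candidates = detect_local_maxima(nuc_s, within=cell_mask)
    stage_counts["candidates"] = len(candidates)

    try:
        bright = filter_peaks_by_intensity(candidates, nuc_s, within=cell_mask)
    except ValueError:  # constant nucleoid channel: nothing detectable
        bright = PeakSet.empty()
    stage_counts["after_intensity_filter"] = len(bright)

    sph = cfg.spheroid
    unique = dedup_peaks(bright, sph, nuc_s.voxel_size)
    stage_counts["after_dedup"] = len(unique)

    validated = iterative_welch_filter(unique, nuc_s, mito_norm, seg.mask, sph, cfg)
    stage_counts["after_welch"] = len(validated)

    return CellResult(
        cell_id,
        len(validated),
        seg.volume_voxels,
        seg.volume_um3,
        seg.fragments,
        validated,
        stage_counts,
    )
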