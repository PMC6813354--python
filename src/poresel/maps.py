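"""3D particle-density maps, enrichment classification, and sidechain states.

Equilibrium snapshots of cation positions are voxelized into a number
density (particles/Å³). Voxels are then classified by their enrichment
over the bulk density: a ratio of e¹ ≈ 2.72 corresponds to a 1 k_BT
binding preference, e³ ≈ 20.1 to 3 k_BT — the conventional iso-levels
for drawing weak- and strong-binding meshes. The module also counts
selectivity-filter occupancy per frame and classifies the filter
glutamate's sidechain between its upward and inward-facing ("dunked")
rotameric states from the (χ1, χ2) dihedral pair.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

#: Density-over-bulk ratio equivalent to a 1 k_BT binding preference.
WEAK_RATIO = math.e
#: Density-over-bulk ratio equivalent to a 3 k_BT binding preference.
STRONG_RATIO = math.e**3

#: Sidechain dihedral windows (degrees, closed intervals, angles in [0, 360)).
UPWARD_CHI1 = (60.0, 180.0)
UPWARD_CHI2 = (0.0, 90.0)
DUNKED_CHI1 = (140.0, 200.0)
DUNKED_CHI2 = (290.0, 330.0)

LABEL_BULK, LABEL_WEAK, LABEL_STRONG = 0, 1, 2


@dataclass
class ParticleCloud:
    """Positions of tracked particles across simulation frames.

    ``positions`` is (N, 3) in Å; ``frame_index`` maps each row to its
    frame in [0, n_frames). Frames with no particles are legal.
    """

    positions: np.ndarray
    frame_index: np.ndarray
    n_frames: int

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.frame_index = np.asarray(self.frame_index, dtype=int).reshape(-1)
        if len(self.positions) != len(self.frame_index):
            raise ValueError("positions and frame_index lengths differ")
        if self.n_frames < 0:
            raise ValueError("n_frames must be non-negative")
        if len(self.frame_index) and (
            self.frame_index.min() < 0 or self.frame_index.max() >= self.n_frames
        ):
            raise ValueError("frame_index out of range")
        if len(self.positions) and not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")

    @property
    def n_particles(self) -> int:
        return len(self.positions)


@dataclass
class DensityGrid:
    """Voxelized particle number density with a bulk reference.

    ``density`` holds particles/Å³ per voxel, averaged over frames.
    ``bulk_density`` is the mean density over the designated bulk region
    and anchors the k_BT enrichment thresholds.
    """

    edges: tuple[np.ndarray, np.ndarray, np.ndarray]
    density: np.ndarray
    n_frames: int
    bulk_density: float
    bulk_region: tuple[float, float]
    n_outside: int = 0

    @property
    def origin(self) -> np.ndarray:
        return np.array([e[0] for e in self.edges])

    @property
    def voxel_size(self) -> np.ndarray:
        return np.array([e[1] - e[0] for e in self.edges])

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel_size))

    def centers(self, axis: int) -> np.ndarray:
        e = self.edges[axis]
        return 0.5 * (e[:-1] + e[1:])

    def integrated_count(self) -> float:
        """Mean in-grid particle count per frame (density · volume)."""
        return float(self.density.sum() * self.voxel_volume)


@dataclass
class IsoClassification:
    """Per-voxel enrichment labels: 0 bulk-like, 1 weak (≥1 k_BT), 2 strong (≥3 k_BT)."""

    labels: np.ndarray
    weak_ratio: float = WEAK_RATIO
    strong_ratio: float = STRONG_RATIO

    @property
    def weak_mask(self) -> np.ndarray:
        """Voxels at or above the 1 k_BT level (includes strong ones)."""
        return self.labels >= LABEL_WEAK

    @property
    def strong_mask(self) -> np.ndarray:
        return self.labels >= LABEL_STRONG


@dataclass
class SFRegion:
    """Counting region for selectivity-filter occupancy.

    An axial slab combined with a radial cutoff about the pore axis.
    The default bounds (z in [0, 8] Å, radius 5 Å about x=y=0) are a
    documented convention and should be confirmed against the system's
    geometry for real data.
    """

    z_lo: float = 0.0
    z_hi: float = 8.0
    radial_cutoff: float = 5.0
    axis_xy: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not (np.isfinite(self.z_lo) and np.isfinite(self.z_hi)
                and np.isfinite(self.radial_cutoff)):
            raise ValueError("region bounds must be finite")
        if self.z_hi <= self.z_lo:
            raise ValueError("z_hi must exceed z_lo")

    def contains(self, positions: np.ndarray) -> np.ndarray:
        positions = np.asarray(positions, dtype=float).reshape(-1, 3)
        dx = positions[:, 0] - self.axis_xy[0]
        dy = positions[:, 1] - self.axis_xy[1]
        in_slab = (positions[:, 2] >= self.z_lo) & (positions[:, 2] <= self.z_hi)
        in_rad = dx**2 + dy**2 <= self.radial_cutoff**2
        return in_slab & in_rad


@dataclass
class OccupancyStat:
    """Per-frame particle counts inside a region, with mean and population SD."""

    region: SFRegion
    counts: np.ndarray
    mean: float
    sd: float


@dataclass
class DihedralTrace:
    """(χ1, χ2) sidechain dihedral time series, degrees wrapped to [0, 360)."""

    chi1: np.ndarray
    chi2: np.ndarray
    true_states: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.chi1 = np.mod(np.asarray(self.chi1, dtype=float), 360.0)
        self.chi2 = np.mod(np.asarray(self.chi2, dtype=float), 360.0)
        if self.chi1.shape != self.chi2.shape:
            raise ValueError("chi1 and chi2 must have the same length")

    def __len__(self) -> int:
        return len(self.chi1)


@dataclass
class DihedralClassification:
    """Frame-by-frame rotamer labels and the dunked-state fraction."""

    labels: np.ndarray  # array of 'up' | 'dunked' | 'other'
    dunked_fraction: float
    upward_fraction: float


def build_density(
    cloud: ParticleCloud,
    voxel_size: float,
    bounds: tuple[tuple[float, float], tuple[float, float], tuple[float, float]],
    bulk_region: tuple[float, float] | None = None,
) -> DensityGrid:
    """Voxelize a particle cloud into a number-density grid.

    Parameters
    ----------
    cloud
        Particle positions with frame indices.
    voxel_size
        Cubic voxel edge length in Å (each axis span is snapped up to a
        whole number of voxels).
    bounds
        ``((x_lo, x_hi), (y_lo, y_hi), (z_lo, z_hi))`` of the grid.
    bulk_region
        Axial slab ``(z_lo, z_hi)`` used to estimate the bulk density.
        Defaults to the outermost 2 Å at the upper-z (extracellular)
        edge of the grid — confirm for real data.

    Density is count / (n_frames · voxel volume); particles outside the
    bounds are counted in ``n_outside`` and reported with a warning, not
    silently dropped.
    """
    if cloud.n_frames < 1:
        raise ValueError("need at least one frame to build a density")
    if voxel_size <= 0:
        raise ValueError("voxel_size must be positive")
    edges = []
    for lo, hi in bounds:
        if hi <= lo:
            raise ValueError(f"empty grid axis: [{lo}, {hi}]")
        n = max(1, int(round((hi - lo) / voxel_size)))
        edges.append(np.linspace(lo, lo + n * voxel_size, n + 1))
    edges = tuple(edges)

    counts, _ = np.histogramdd(cloud.positions, bins=edges)
    n_in = int(counts.sum())
    n_outside = cloud.n_particles - n_in
    if n_outside:
        warnings.warn(
            f"{n_outside} of {cloud.n_particles} particles fall outside the "
            "density grid bounds and are excluded", stacklevel=2)

    voxel_volume = float(np.prod([e[1] - e[0] for e in edges]))
    density = counts / (cloud.n_frames * voxel_volume)

    if bulk_region is None:
        z_hi = edges[2][-1]
        bulk_region = (z_hi - 2.0, z_hi)
    zc = 0.5 * (edges[2][:-1] + edges[2][1:])
    bulk_mask = (zc >= bulk_region[0]) & (zc <= bulk_region[1])
    if not bulk_mask.any():
        raise ValueError(
            f"bulk region {bulk_region} contains no voxel centers; widen it")
    bulk_density = float(density[:, :, bulk_mask].mean())
    if bulk_density <= 0:
        raise ValueError("bulk region holds no particles; bulk density is zero")

    return DensityGrid(
        edges=edges, density=density, n_frames=cloud.n_frames,
        bulk_density=bulk_density, bulk_region=tuple(bulk_region),
        n_outside=n_outside,
    )


def classify_iso(grid: DensityGrid) -> IsoClassification:
    """Label voxels by enrichment over bulk at the 1 and 3 k_BT levels.

    A voxel at density ratio exactly e¹ (2.718…) is weak; at or above e³
    it is strong. Strong voxels are a subset of weak ones by construction.
    """
    ratio = grid.density / grid.bulk_density
    labels = np.zeros(grid.density.shape, dtype=np.int8)
    labels[ratio >= WEAK_RATIO] = LABEL_WEAK
    labels[ratio >= STRONG_RATIO] = LABEL_STRONG
    return IsoClassification(labels=labels)


def occupancy(cloud: ParticleCloud, region: SFRegion | None = None) -> OccupancyStat:
    """Per-frame particle count inside the selectivity-filter region.

    Returns the mean and population standard deviation of the per-frame
    counts; for an empty cloud both are zero.
    """
    region = region or SFRegion()
    if cloud.n_frames == 0:
        return OccupancyStat(region=region, counts=np.zeros(0, dtype=int),
                             mean=0.0, sd=0.0)
    if cloud.n_particles:
        inside = region.contains(cloud.positions)
        counts = np.bincount(cloud.frame_index[inside], minlength=cloud.n_frames)
    else:
        counts = np.zeros(cloud.n_frames, dtype=int)
    return OccupancyStat(region=region, counts=counts,
                         mean=float(counts.mean()), sd=float(counts.std()))


def classify_dihedrals(trace: DihedralTrace) -> DihedralClassification:
    """Classify each frame as upward, dunked, or other.

    Upward: χ1 ∈ [60, 180] and χ2 ∈ [0, 90]. Dunked: χ1 ∈ [140, 200]
    and χ2 ∈ [290, 330]. Intervals are closed; the χ2 windows are
    disjoint, so the χ1 overlap [140, 180] is unambiguous.
    """
    chi1, chi2 = trace.chi1, trace.chi2
    up = ((chi1 >= UPWARD_CHI1[0]) & (chi1 <= UPWARD_CHI1[1])
          & (chi2 >= UPWARD_CHI2[0]) & (chi2 <= UPWARD_CHI2[1]))
    dunk = ((chi1 >= DUNKED_CHI1[0]) & (chi1 <= DUNKED_CHI1[1])
            & (chi2 >= DUNKED_CHI2[0]) & (chi2 <= DUNKED_CHI2[1]))
    labels = np.full(len(trace), "other", dtype=object)
    labels[up] = "up"
    labels[dunk] = "dunked"
    n = max(len(trace), 1)
    return DihedralClassification(
        labels=labels,
        dunked_fraction=float(dunk.sum()) / n,
        upward_fraction=float(up.sum()) / n,
    )
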