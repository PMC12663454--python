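"""Synthetic 3D fluorescence stacks with known puncta ground truth.

Emulates, at desk scale, confocal acquisition of cells whose peroxisomes
appear as diffraction-limited puncta: non-overlapping ellipsoidal cells are
placed in the volume, anisotropic 3D Gaussian spots are placed strictly
inside each cell with a minimum pairwise separation, and the rendered stack
is ``background + sum of Gaussians`` with optional Poisson (shot) noise and
additive Gaussian (read) noise.  The returned :class:`GroundTruth` carries
the exact spot centroids, per-cell counts, the cell label volume (standing
in for a learned segmentation) and the true numerical density.

Conventions: arrays are (z, y, x); voxel indices are 0-based; the physical
position of a voxel center is ``(index + 0.5) * voxel_size`` in micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..imaging import ImageStack3D
from .counts import CountSimParams, gen_count_table, with_seed


class PlacementError(RuntimeError):
    """Cells or spots could not be placed under the separation constraints."""


@dataclass(frozen=True)
class ImageSimParams:
    shape: tuple[int, int, int] = (31, 256, 256)  # (z, y, x) voxels
    voxel_size: tuple[float, float, float] = (0.2, 0.0509, 0.0509)  # um
    n_cells: int = 4
    cell_geometry: tuple[float, float, float] = (1.5, 2.0, 2.0)  # semi-axes, um
    spots_per_cell: int | CountSimParams = 3
    spot_sigma: tuple[float, float, float] = (0.25, 0.11, 0.11)  # um
    spot_amplitude: float = 500.0
    background: float = 100.0
    poisson_noise: bool = True
    gaussian_noise_sd: float = 0.0
    min_spot_separation: float = 0.6  # um
    lateral_margin_um: float = 0.2  # keeps cells off the y/x borders
    seed: int = 0
    max_tries: int = 500

    def __post_init__(self):
        if any(s < 1 for s in self.shape):
            raise ValueError("all stack dimensions must be >= 1")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel size components must be positive")
        if any(a <= 0 for a in self.cell_geometry):
            raise ValueError("cell semi-axes must be positive")
        for sig, d in zip(self.spot_sigma, self.voxel_size):
            if sig < d:
                raise ValueError(
                    f"spot sigma {sig} um below one voxel ({d} um): unresolvable"
                )
        if self.spot_amplitude < 0 or self.background < 0:
            raise ValueError("amplitude and background must be non-negative")

    @property
    def snr(self) -> float:
        """Peak amplitude over the noise s.d. at the spot peak."""
        var = self.gaussian_noise_sd**2
        if self.poisson_noise:
            var += self.background + self.spot_amplitude
        return self.spot_amplitude / np.sqrt(var) if var > 0 else np.inf


@dataclass
class GroundTruth:
    spot_centroids: np.ndarray  # (N, 3) physical um, (z, y, x)
    per_cell_counts: dict[int, int]
    cell_label_volume: np.ndarray
    true_density: float  # spots per um^3 of cytoplasm
    cytoplasmic_volume_um3: float
    spot_cells: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))


def _paint_ellipsoid(labels, center_um, semi_axes, voxel_size, value):
    lo = []
    hi = []
    for c, a, d, n in zip(center_um, semi_axes, voxel_size, labels.shape):
        lo.append(max(0, int(np.floor((c - a) / d - 1))))
        hi.append(min(n, int(np.ceil((c + a) / d + 1))))
    zz, yy, xx = np.meshgrid(
        *(np.arange(l, h) for l, h in zip(lo, hi)), indexing="ij"
    )
    coords = [(zz + 0.5) * voxel_size[0], (yy + 0.5) * voxel_size[1], (xx + 0.5) * voxel_size[2]]
    r2 = sum(((c - m) / a) ** 2 for c, m, a in zip(coords, center_um, semi_axes))
    sel = r2 <= 1.0
    labels[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]][sel] = value


def _place_cells(rng, params: ImageSimParams) -> np.ndarray:
    """Rejection-sample non-overlapping ellipsoid centers (um)."""
    extent = np.array(params.shape) * np.array(params.voxel_size)
    axes = np.array(params.cell_geometry)
    lo = axes.copy()
    hi = extent - axes
    lo[1:] += params.lateral_margin_um
    hi[1:] -= params.lateral_margin_um
    if np.any(hi <= lo):
        raise PlacementError("cell geometry does not fit inside the volume")
    centers = []
    for i in range(params.n_cells):
        for _ in range(params.max_tries):
            c = lo + rng.random(3) * (hi - lo)
            # identical axis-aligned ellipsoids: disjoint iff scaled distance >= 2
            if all(np.linalg.norm((c - o) / axes) >= 2.0 for o in centers):
                centers.append(c)
                break
        else:
            raise PlacementError(
                f"placed only {i} of {params.n_cells} cells without overlap"
            )
    return np.array(centers)


def _spot_counts(rng, params: ImageSimParams) -> np.ndarray:
    spec = params.spots_per_cell
    if isinstance(spec, CountSimParams):
        sub = with_seed(spec, int(rng.integers(0, 2**31 - 1)))
        table = gen_count_table(sub)
        counts = table["count"].to_numpy()
        if len(counts) < params.n_cells:
            raise ValueError("CountSimParams draw produced fewer cells than needed")
        return counts[: params.n_cells]
    if int(spec) < 0:
        raise ValueError("spots_per_cell must be non-negative")
    return np.full(params.n_cells, int(spec), dtype=int)


def _place_spots(rng, centers, counts, labels, params: ImageSimParams):
    axes = np.array(params.cell_geometry)
    d = np.array(params.voxel_size)
    placed: list[np.ndarray] = []
    cells: list[int] = []
    for i, (center, n_spots) in enumerate(zip(centers, counts)):
        for _ in range(int(n_spots)):
            ok = False
            for _ in range(params.max_tries):
                # uniform in the unit ball, scaled to the ellipsoid interior
                v = rng.normal(size=3)
                v /= np.linalg.norm(v)
                r = rng.random() ** (1.0 / 3.0)
                pos = center + v * r * axes * 0.92  # stay clear of the surface
                vox = np.floor(pos / d).astype(int)
                if np.any(vox < 0) or np.any(vox >= labels.shape):
                    continue
                if labels[tuple(vox)] != i + 1:
                    continue
                if all(
                    np.linalg.norm(pos - q) >= params.min_spot_separation for q in placed
                ):
                    ok = True
                    break
            if not ok:
                raise PlacementError(
                    f"could not place spot under separation "
                    f"{params.min_spot_separation} um; achieved {len(placed)} spots"
                )
            placed.append(pos)
            cells.append(i + 1)
    return np.array(placed).reshape(-1, 3), np.array(cells, dtype=int)


def _render(stack, centroids, params: ImageSimParams):
    d = np.array(params.voxel_size)
    sig = np.array(params.spot_sigma)
    half = np.ceil(4.5 * sig / d).astype(int)
    for pos in centroids:
        cvox = np.floor(pos / d).astype(int)
        lo = np.maximum(cvox - half, 0)
        hi = np.minimum(cvox + half + 1, stack.shape)
        grids = [
            (np.arange(l, h) + 0.5) * dd for l, h, dd in zip(lo, hi, d)
        ]
        zz, yy, xx = np.meshgrid(*grids, indexing="ij")
        q = (
            (zz - pos[0]) ** 2 / (2 * sig[0] ** 2)
            + (yy - pos[1]) ** 2 / (2 * sig[1] ** 2)
            + (xx - pos[2]) ** 2 / (2 * sig[2] ** 2)
        )
        stack[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] += (
            params.spot_amplitude * np.exp(-q)
        )


def gen_image_stack(params: ImageSimParams) -> tuple[ImageStack3D, GroundTruth]:
    """Generate a stack and its exact ground truth.

    Deterministic in (params, seed).  Raises :class:`PlacementError`, with
    the achieved spot count, when the requested configuration cannot be
    placed under the separation constraint.
    """
    rng = np.random.default_rng(params.seed)
    labels = np.zeros(params.shape, dtype=np.int32)
    centers = _place_cells(rng, params)
    for i, c in enumerate(centers):
        _paint_ellipsoid(labels, c, params.cell_geometry, params.voxel_size, i + 1)

    counts = _spot_counts(rng, params)
    centroids, spot_cells = _place_spots(rng, centers, counts, labels, params)

    stack = np.full(params.shape, float(params.background))
    _render(stack, centroids, params)

    if params.poisson_noise:
        stack = rng.poisson(stack).astype(float)
    if params.gaussian_noise_sd > 0:
        stack = stack + rng.normal(0.0, params.gaussian_noise_sd, size=stack.shape)
    stack = np.clip(stack, 0.0, None)

    voxel_volume = float(np.prod(params.voxel_size))
    cyto_volume = float(np.count_nonzero(labels)) * voxel_volume
    per_cell = {i + 1: int(c) for i, c in enumerate(counts)}
    truth = GroundTruth(
        spot_centroids=centroids,
        per_cell_counts=per_cell,
        cell_label_volume=labels,
        true_density=len(centroids) / cyto_volume if cyto_volume > 0 else 0.0,
        cytoplasmic_volume_um3=cyto_volume,
        spot_cells=spot_cells,
    )
    return ImageStack3D(voxels=stack, voxel_size=params.voxel_size), truth
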