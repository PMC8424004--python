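"""Synthetic 2D left-atrial tissue substrates.

The left atrium is represented as a standardised disk on a square pixel
grid: conductive tissue inside the disk, with four non-conductive holes for
the pulmonary veins (PVs) and one for the left atrial appendage (LAA).
Fibrosis is a patchy binary field inside the tissue; it conducts slowly,
which is modelled by a reduced diffusion coefficient.  All geometry is
row-major with the origin at the top-left, 0-based ``(row, col)`` indices,
and a default pixel spacing of 0.3 mm (a 150-pixel disk is 45 mm across).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "TissueModel",
    "IntensityMap",
    "SynthesisConfig",
    "TissueIOError",
    "D_HEALTHY",
    "D_FIBROTIC",
    "build_disk_geometry",
    "synthesize_fibrosis",
    "threshold_fibrosis",
    "build_diffusion_map",
    "make_reference_lesions",
    "save_tissue",
    "load_tissue",
    "load_intensity_nifti",
    "export_png",
]

#: Monodomain diffusion coefficients, mm^2 per unit simulation time.
#: Healthy atrial tissue conducts ~6.7x faster than fibrotic patches.
D_HEALTHY = 0.05
D_FIBROTIC = 0.0075


class TissueIOError(ValueError):
    """Raised when a tissue archive is missing, truncated or inconsistent."""


@dataclass(frozen=True)
class SynthesisConfig:
    """Parameters of the synthetic disk generator.

    Hole positions are canonical fractions of the grid: two superior PVs in
    the upper half, two inferior PVs in the lower half, the appendage at
    mid-left.  All radii scale linearly with ``grid_size`` so the same
    layout is produced at any resolution.
    """

    grid_size: int = 150
    disk_radius: float | None = None  # pixels; default 70/150 of grid
    pv_radius: float | None = None  # pixels; default 7/150 of grid
    laa_radius: float | None = None  # pixels; default 9/150 of grid
    fibrosis_fraction: float = 0.25
    correlation_length: float = 6.0  # Gaussian smoothing scale, pixels
    seed: int = 0
    pixel_spacing: float = 0.3  # mm per pixel

    # Canonical layout (fractions of grid_size): disk centre, PV ring
    # radius, PV angles (deg, 0 = +col axis, increasing towards +row),
    # LAA position.
    _PV_RING_FRACTION = 48.0 / 150.0
    _PV_ANGLES_DEG = (225.0, 315.0, 135.0, 45.0)  # LSPV, RSPV, LIPV, RIPV
    _LAA_ANGLE_DEG = 180.0

    def resolved(self) -> "SynthesisConfig":
        """Fill radius defaults scaled to the grid size."""
        s = self.grid_size
        return dataclasses.replace(
            self,
            disk_radius=self.disk_radius if self.disk_radius is not None else 70.0 * s / 150.0,
            pv_radius=self.pv_radius if self.pv_radius is not None else 7.0 * s / 150.0,
            laa_radius=self.laa_radius if self.laa_radius is not None else 9.0 * s / 150.0,
        )


@dataclass
class TissueModel:
    """Static substrate of one episode.

    ``mask`` is True on conductive atrial tissue; ``fibrosis`` is a subset
    of the mask; ``diffusion`` holds the per-pixel monodomain coefficient
    (0 off-mask, exactly two positive values on-mask before any ablation).
    """

    mask: np.ndarray
    fibrosis: np.ndarray
    diffusion: np.ndarray
    pixel_spacing: float = 0.3
    pv_centres: list[tuple[float, float]] = field(default_factory=list)
    laa_centre: tuple[float, float] | None = None
    reference_lesions: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.fibrosis = np.asarray(self.fibrosis, dtype=bool)
        self.diffusion = np.asarray(self.diffusion, dtype=np.float64)
        if self.reference_lesions is None:
            self.reference_lesions = np.zeros_like(self.mask)
        else:
            self.reference_lesions = np.asarray(self.reference_lesions, dtype=bool)
        shapes = {a.shape for a in (self.mask, self.fibrosis, self.diffusion, self.reference_lesions)}
        if len(shapes) != 1:
            raise TissueIOError(f"grid shape mismatch between fields: {sorted(shapes)}")
        if self.mask.ndim != 2:
            raise ValueError(f"tissue grid must be 2D, got {self.mask.shape}")
        if np.any(self.fibrosis & ~self.mask):
            raise ValueError("fibrosis outside the conductive mask")
        if np.any(self.diffusion[~self.mask] != 0.0):
            raise ValueError("non-zero diffusion outside the conductive mask")
        if np.any(self.diffusion < 0):
            raise ValueError("negative diffusion coefficient")

    @property
    def grid_size(self) -> int:
        return self.mask.shape[0]

    @property
    def healthy(self) -> np.ndarray:
        """Conductive, non-fibrotic pixels."""
        return self.mask & ~self.fibrosis

    def copy(self) -> "TissueModel":
        return TissueModel(
            mask=self.mask.copy(),
            fibrosis=self.fibrosis.copy(),
            diffusion=self.diffusion.copy(),
            pixel_spacing=self.pixel_spacing,
            pv_centres=list(self.pv_centres),
            laa_centre=self.laa_centre,
            reference_lesions=self.reference_lesions.copy(),
            meta=dict(self.meta),
        )

    def __eq__(self, other) -> bool:  # bit-exact field equality
        if not isinstance(other, TissueModel):
            return NotImplemented
        return (
            np.array_equal(self.mask, other.mask)
            and np.array_equal(self.fibrosis, other.fibrosis)
            and np.array_equal(self.diffusion, other.diffusion)
            and np.array_equal(self.reference_lesions, other.reference_lesions)
            and self.pixel_spacing == other.pixel_spacing
            and [tuple(c) for c in self.pv_centres] == [tuple(c) for c in other.pv_centres]
            and (tuple(self.laa_centre) if self.laa_centre else None)
            == (tuple(other.laa_centre) if other.laa_centre else None)
        )


@dataclass(frozen=True)
class IntensityMap:
    """An LGE-like signal-intensity image plus its blood-pool reference.

    The image intensity ratio (IIR) of a pixel is value / blood_pool_mean;
    fibrosis is declared where the IIR exceeds a chosen threshold.
    """

    values: np.ndarray
    blood_pool_mean: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=np.float64))
        if not np.all(np.isfinite(self.values)):
            raise ValueError("intensity values must be finite")
        if np.any(self.values < 0):
            raise ValueError("intensity values must be non-negative")
        if not self.blood_pool_mean > 0:
            raise ValueError("blood_pool_mean must be positive")


def _disc(shape: tuple[int, int], centre: tuple[float, float], radius: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - centre[0]) ** 2 + (cc - centre[1]) ** 2 <= radius**2


def build_disk_geometry(cfg: SynthesisConfig) -> TissueModel:
    """Construct the disk mask with four PV holes and one LAA hole.

    Raises ``ValueError`` for grids under 50 pixels, overlapping holes, or
    holes touching the outer boundary of the disk.
    """
    cfg = cfg.resolved()
    if cfg.grid_size < 50:
        raise ValueError(f"grid_size must be >= 50, got {cfg.grid_size}")
    s = cfg.grid_size
    centre = ((s - 1) / 2.0, (s - 1) / 2.0)
    ring = cfg._PV_RING_FRACTION * s

    pv_centres = []
    for ang in cfg._PV_ANGLES_DEG:
        a = math.radians(ang)
        pv_centres.append((centre[0] + ring * math.sin(a), centre[1] + ring * math.cos(a)))
    a = math.radians(cfg._LAA_ANGLE_DEG)
    laa_centre = (centre[0] + ring * math.sin(a), centre[1] + ring * math.cos(a))

    holes = [(c, cfg.pv_radius) for c in pv_centres] + [(laa_centre, cfg.laa_radius)]
    # Geometric sanity: holes must stay strictly inside the disk and apart.
    for (c, r) in holes:
        if r > 0:
            d = math.hypot(c[0] - centre[0], c[1] - centre[1])
            if d + r >= cfg.disk_radius:
                raise ValueError("hole touches or crosses the outer disk boundary")
    for i, (ci, ri) in enumerate(holes):
        for (cj, rj) in holes[i + 1 :]:
            if ri > 0 and rj > 0:
                if math.hypot(ci[0] - cj[0], ci[1] - cj[1]) <= ri + rj:
                    raise ValueError("holes overlap or touch")

    mask = _disc((s, s), centre, cfg.disk_radius)
    for (c, r) in holes:
        if r > 0:
            mask &= ~_disc((s, s), c, r)

    return TissueModel(
        mask=mask,
        fibrosis=np.zeros((s, s), dtype=bool),
        diffusion=np.zeros((s, s), dtype=np.float64),
        pixel_spacing=cfg.pixel_spacing,
        pv_centres=pv_centres,
        laa_centre=laa_centre,
        meta={
            "grid_size": s,
            "disk_radius": cfg.disk_radius,
            "pv_radius": cfg.pv_radius,
            "laa_radius": cfg.laa_radius,
            "seed": cfg.seed,
        },
    )


def synthesize_fibrosis(geom: TissueModel, cfg: SynthesisConfig) -> TissueModel:
    """Add a spatially correlated patchy fibrosis field to a bare geometry.

    Seeded white noise is Gaussian-smoothed at ``correlation_length`` pixels
    and thresholded at the empirical quantile that yields the target area
    fraction of the conductive mask; the output is bit-reproducible for a
    fixed (config, seed) pair.
    """
    if geom.fibrosis.any():
        raise ValueError("geometry already carries a fibrosis map")
    if not 0 <= cfg.fibrosis_fraction < 1:
        raise ValueError(f"fibrosis_fraction must be in [0, 1), got {cfg.fibrosis_fraction}")
    out = geom.copy()
    if cfg.fibrosis_fraction == 0:
        out.meta.update(fibrosis_fraction=0.0, seed=cfg.seed)
        return out
    rng = np.random.default_rng(cfg.seed)
    noise = rng.standard_normal(geom.mask.shape)
    smooth = ndimage.gaussian_filter(noise, sigma=cfg.correlation_length, mode="reflect")
    vals = smooth[geom.mask]
    thr = np.quantile(vals, 1.0 - cfg.fibrosis_fraction)
    out.fibrosis = geom.mask & (smooth >= thr)
    out.meta.update(fibrosis_fraction=cfg.fibrosis_fraction, seed=cfg.seed)
    return out


def threshold_fibrosis(img: IntensityMap, mask: np.ndarray, ratio_threshold: float) -> np.ndarray:
    """Binary fibrosis from an intensity map by image-intensity-ratio thresholding.

    A pixel is fibrotic iff it lies on the mask and its intensity divided by
    the blood-pool mean is at least ``ratio_threshold``.  Monotone: raising
    the threshold never adds fibrotic pixels.
    """
    if not ratio_threshold > 0:
        raise ValueError("ratio_threshold must be positive")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != img.values.shape:
        raise ValueError("mask and intensity map shapes differ")
    return mask & (img.values / img.blood_pool_mean >= ratio_threshold)


def build_diffusion_map(
    geom: TissueModel,
    d_healthy: float = D_HEALTHY,
    d_fibrotic: float = D_FIBROTIC,
) -> TissueModel:
    """Assign the two-level diffusion field: fast healthy tissue, slow fibrosis.

    Off-mask pixels get exactly 0.  Requires ``d_healthy > d_fibrotic > 0``.
    """
    if not (d_healthy > d_fibrotic > 0):
        raise ValueError(
            f"need d_healthy > d_fibrotic > 0, got {d_healthy}, {d_fibrotic}"
        )
    out = geom.copy()
    diff = np.zeros_like(out.diffusion)
    diff[out.mask] = d_healthy
    diff[out.fibrosis] = d_fibrotic
    out.diffusion = diff
    out.meta.update(d_healthy=d_healthy, d_fibrotic=d_fibrotic)
    return out


def make_reference_lesions(geom: TissueModel, ring_width: float = 3.0) -> np.ndarray:
    """PV-encircling lesion rings (a pulmonary-vein-isolation surrogate).

    Returns a binary grid of annuli of ``ring_width`` pixels around each PV
    hole, clipped to the conductive mask.  These stand in for pre-determined
    successful lesions and feed only the training-time shaping reward.
    """
    lesions = np.zeros_like(geom.mask)
    if ring_width <= 0:
        return lesions
    pv_r = geom.meta.get("pv_radius", 7.0 * geom.grid_size / 150.0)
    for c in geom.pv_centres:
        ring = _disc(geom.mask.shape, c, pv_r + ring_width) & ~_disc(geom.mask.shape, c, pv_r)
        lesions |= ring
    return lesions & geom.mask


_ARRAY_FIELDS = ("mask", "fibrosis", "diffusion", "reference_lesions")


def save_tissue(tissue: TissueModel, path: str | Path) -> Path:
    """Write a tissue to a single-archive ``.npz`` file with JSON metadata."""
    path = Path(path)
    meta = {
        "format": "ablateq-tissue",
        "version": 1,
        "pixel_spacing": tissue.pixel_spacing,
        "pv_centres": [list(c) for c in tissue.pv_centres],
        "laa_centre": list(tissue.laa_centre) if tissue.laa_centre else None,
        "meta": tissue.meta,
    }
    arrays = {f: getattr(tissue, f) for f in _ARRAY_FIELDS}
    with open(path, "wb") as fh:
        np.savez(fh, _meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)
    return path


def load_tissue(path: str | Path) -> TissueModel:
    """Read a tissue archive; inverse of :func:`save_tissue` bit-for-bit."""
    path = Path(path)
    if not path.exists():
        raise TissueIOError(f"no such tissue file: {path}")
    try:
        with np.load(path) as npz:
            missing = [k for k in _ARRAY_FIELDS + ("_meta",) if k not in npz.files]
            if missing:
                raise TissueIOError(f"tissue archive missing fields: {missing}")
            arrays = {f: npz[f] for f in _ARRAY_FIELDS}
            meta = json.loads(bytes(npz["_meta"]).decode())
    except TissueIOError:
        raise
    except Exception as exc:  # zipfile/pickle/json failures on corrupt input
        raise TissueIOError(f"corrupt or unreadable tissue archive {path}: {exc}") from None
    if meta.get("format") != "ablateq-tissue":
        raise TissueIOError(f"{path} is not an ablateq tissue archive")
    return TissueModel(
        mask=arrays["mask"],
        fibrosis=arrays["fibrosis"],
        diffusion=arrays["diffusion"],
        pixel_spacing=meta["pixel_spacing"],
        pv_centres=[tuple(c) for c in meta["pv_centres"]],
        laa_centre=tuple(meta["laa_centre"]) if meta["laa_centre"] else None,
        reference_lesions=arrays["reference_lesions"],
        meta=meta.get("meta", {}),
    )


def load_intensity_nifti(path: str | Path, blood_pool_mean: float,
                         slice_index: int | None = None) -> IntensityMap:
    """Read a 2D (or one slice of a 3D) NIfTI volume as an intensity map."""
    import nibabel as nib

    img = np.asanyarray(nib.load(str(path)).dataobj).astype(np.float64)
    if img.ndim == 3:
        img = img[:, :, img.shape[2] // 2 if slice_index is None else slice_index]
    if img.ndim != 2:
        raise TissueIOError(f"expected a 2D image or 3D volume, got shape {img.shape}")
    return IntensityMap(values=np.abs(img), blood_pool_mean=blood_pool_mean)


def export_png(tissue: TissueModel, path: str | Path) -> Path:
    """Render mask / fibrosis / diffusion as an RGB inspection image."""
    import imageio.v3 as iio

    s = tissue.grid_size
    img = np.zeros((s, s, 3), dtype=np.uint8)
    img[tissue.mask] = (60, 90, 200)  # healthy: blue
    img[tissue.fibrosis] = (200, 60, 60)  # fibrosis: red
    img[tissue.mask & (tissue.diffusion == 0)] = (230, 220, 60)  # ablated: yellow
    iio.imwrite(Path(path), img)
    return Path(path)
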