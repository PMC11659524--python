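"""Whole-slide preprocessing: tissue masking, tessellation, stain normalization.

The pipeline converts an H&E slide into a bag of tile embeddings:

1. tissue segmentation — Otsu threshold on the median-blurred saturation
   channel of the HSV transform, at a coarse downsample;
2. tessellation — non-overlapping tiles of fixed *physical* size (default
   256 µm, i.e. 512 px at 0.5 µm/px), keeping tiles with >25% tissue;
3. Macenko stain normalization — stain vectors estimated per tile from the
   optical-density eigen-plane and mapped to a reference H&E basis;
4. per-tile standardization to zero mean / unit variance;
5. embedding through a pluggable tile encoder into a :class:`~histotme.bags.TileBag`.

Foundation-model encoders (CTransPath / RetCCL / UNI) plug in behind the
same embedder contract; the bundled :class:`SyntheticEmbedder` is a
deterministic stand-in used for testing and examples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np
from scipy.ndimage import median_filter
from skimage.color import rgb2hsv
from skimage.filters import threshold_otsu

from .bags import TileBag

logger = logging.getLogger(__name__)


class NotEnoughStainError(RuntimeError):
    """Tile has too few stained pixels to estimate a stain basis."""


# Reference H&E stain basis (columns H then E, unit norm) and robust
# concentration maxima; the widely used defaults for Macenko mapping.
DEFAULT_REFERENCE_BASIS = np.array(
    [[0.5626, 0.2159],
     [0.7201, 0.8012],
     [0.4062, 0.5581]]
)
DEFAULT_REFERENCE_MAXC = np.array([1.9705, 1.0308])


@dataclass
class StainBasis:
    """Two unit-norm stain OD vectors (columns: H, E) + robust concentration maxima."""

    vectors: np.ndarray  # (3, 2)
    max_concentrations: np.ndarray  # (2,)


@dataclass
class TissueMask:
    """Binary tissue mask on a downsampled grid of the level-0 slide frame."""

    mask: np.ndarray  # (h, w) bool; rows = y
    downsample: int
    mpp: float  # microns per pixel at level 0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mpp is not None and np.isfinite(self.mpp) and not self.mpp > 0:
            raise ValueError("mpp must be positive")

    @property
    def slide_shape(self) -> tuple[int, int]:
        """(height, width) of the level-0 frame implied by the mask."""
        return (self.mask.shape[0] * self.downsample, self.mask.shape[1] * self.downsample)


@dataclass
class TileGrid:
    """Retained tile positions on a non-overlapping level-0 grid."""

    tile_um: float
    tile_px: int
    coords: np.ndarray  # (n, 2) int64, (x, y) top-left, level-0 frame
    tissue_fraction: np.ndarray  # (n,) float in [0, 1]
    mpp: float

    def __len__(self) -> int:
        return len(self.coords)


def segment_tissue(rgb_image: np.ndarray, downsample: int = 32, median_size: int = 7) -> TissueMask:
    """Segment tissue from background on a thumbnail of the slide.

    The saturation channel of the HSV transform is median-blurred and
    Otsu-thresholded; foreground (tissue) is the high-saturation side.
    ``rgb_image`` is the thumbnail itself, already at ``downsample``; mpp is
    attached later by the caller (see :func:`tessellate`).
    """
    img = np.asarray(rgb_image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an (h, w, 3) RGB image")
    if img.dtype != np.uint8:
        img = np.clip(img, 0, 255).astype(np.uint8)
    sat = rgb2hsv(img)[..., 1]
    sat = median_filter(sat, size=median_size)
    if np.ptp(sat) < 1e-9:
        logger.warning("saturation channel has no contrast; returning empty tissue mask")
        mask = np.zeros(sat.shape, dtype=bool)
    else:
        thr = threshold_otsu(sat)
        mask = sat > thr
    return TissueMask(mask=mask, downsample=downsample, mpp=float("nan"))


def tessellate(
    mask: TissueMask,
    tile_um: float = 256.0,
    min_tissue: float = 0.25,
    mpp: float | None = None,
) -> TileGrid:
    """Lay a non-overlapping tile grid over the slide and keep tissue tiles.

    ``tile_px = round(tile_um / mpp)``; a tile is retained iff the fraction
    of its footprint covered by the tissue mask *strictly* exceeds
    ``min_tissue``. Coordinates are 0-based top-left corners in the level-0
    pixel frame, stride = tile size.
    """
    eff_mpp = mpp if mpp is not None else mask.mpp
    if eff_mpp is None or not np.isfinite(eff_mpp) or eff_mpp <= 0:
        raise ValueError("microns-per-pixel unknown: supply mpp= (or --mpp on the CLI)")
    tile_px = int(round(tile_um / eff_mpp))
    h0, w0 = mask.slide_shape
    ds = mask.downsample
    m = mask.mask.astype(np.float64)
    coords: list[tuple[int, int]] = []
    fracs: list[float] = []
    for y in range(0, h0 - tile_px + 1, tile_px):
        ylo, yhi = y // ds, min((y + tile_px + ds - 1) // ds, m.shape[0])
        for x in range(0, w0 - tile_px + 1, tile_px):
            xlo, xhi = x // ds, min((x + tile_px + ds - 1) // ds, m.shape[1])
            sub = m[ylo:yhi, xlo:xhi]
            frac = float(sub.mean()) if sub.size else 0.0
            if frac > min_tissue:
                coords.append((x, y))
                fracs.append(frac)
    return TileGrid(
        tile_um=tile_um,
        tile_px=tile_px,
        coords=np.asarray(coords, dtype=np.int64).reshape(-1, 2),
        tissue_fraction=np.asarray(fracs, dtype=float),
        mpp=float(eff_mpp),
    )


def _rgb_to_od(rgb: np.ndarray) -> np.ndarray:
    rgb = np.asarray(rgb, dtype=np.float64)
    return -np.log10((rgb + 1.0) / 256.0)


def _od_to_rgb(od: np.ndarray) -> np.ndarray:
    rgb = 256.0 * np.power(10.0, -od) - 1.0
    return np.clip(np.round(rgb), 0, 255).astype(np.uint8)


def macenko_fit(
    tile_rgb: np.ndarray,
    od_min: float = 0.15,
    angular_percentiles: tuple[float, float] = (1.0, 99.0),
    min_stained_frac: float = 0.01,
) -> StainBasis:
    """Estimate the two H&E stain vectors of a tile (Macenko).

    Pixels are converted to optical density; near-transparent pixels (all
    channels below ``od_min``) are discarded; the remaining OD cloud is
    projected onto the plane of its two leading eigenvectors and the stain
    vectors are taken at the extreme angular percentiles. The two vectors
    are returned hematoxylin-first (larger red-channel OD — hematoxylin
    absorbs red light more strongly than eosin).

    Raises :class:`NotEnoughStainError` when fewer than ``min_stained_frac``
    of pixels carry stain or the OD covariance is rank-deficient.
    """
    od = _rgb_to_od(tile_rgb).reshape(-1, 3)
    stained = od[(od > od_min).any(axis=1)]
    if len(stained) < max(1, min_stained_frac * len(od)):
        raise NotEnoughStainError("fewer than 1% of pixels exceed the OD floor")
    cov = np.cov(stained.T)
    evals, evecs = np.linalg.eigh(cov)
    if evals[-2] <= 1e-12:
        raise NotEnoughStainError("OD covariance is rank-deficient (single stain direction)")
    plane = evecs[:, -2:]  # two leading eigenvectors, columns
    # orient the plane so projections fall on one side
    proj = stained @ plane
    phi = np.arctan2(proj[:, 1], proj[:, 0])
    lo, hi = np.percentile(phi, angular_percentiles)
    v1 = plane @ np.array([np.cos(lo), np.sin(lo)])
    v2 = plane @ np.array([np.cos(hi), np.sin(hi)])
    vecs = []
    for v in (v1, v2):
        if v.sum() < 0:  # stain vectors are non-negative OD directions
            v = -v
        vecs.append(v / np.linalg.norm(v))
    v1, v2 = vecs
    # hematoxylin first: larger red-channel OD
    he = np.column_stack([v1, v2] if v1[0] >= v2[0] else [v2, v1])
    conc = np.linalg.lstsq(he, stained.T, rcond=None)[0]
    max_c = np.percentile(np.maximum(conc, 0.0), 99, axis=1)
    return StainBasis(vectors=he, max_concentrations=max_c)


def macenko_normalize(
    tile_rgb: np.ndarray,
    basis: StainBasis,
    reference_basis: np.ndarray = DEFAULT_REFERENCE_BASIS,
    reference_maxc: np.ndarray = DEFAULT_REFERENCE_MAXC,
) -> np.ndarray:
    """Re-express a tile's stain concentrations in a reference H&E basis."""
    shape = np.asarray(tile_rgb).shape
    od = _rgb_to_od(tile_rgb).reshape(-1, 3)
    conc = np.linalg.lstsq(basis.vectors, od.T, rcond=None)[0]
    conc = np.maximum(conc, 0.0)
    scale = np.divide(
        reference_maxc, basis.max_concentrations,
        out=np.ones_like(reference_maxc, dtype=float),
        where=basis.max_concentrations > 1e-12,
    )
    od_new = (reference_basis @ (conc * scale[:, None])).T
    return _od_to_rgb(od_new).reshape(shape)


def standardize_tile(tile: np.ndarray) -> np.ndarray:
    """Scale a tile to zero mean, unit standard deviation (all pixels/channels jointly)."""
    x = np.asarray(tile, dtype=np.float64)
    sd = x.std()
    if sd < 1e-12:
        logger.warning("constant tile: standardization returns all zeros")
        return np.zeros_like(x)
    return (x - x.mean()) / sd


class Embedder(Protocol):
    """Contract for tile encoders: batch of standardized tiles -> (b, dim) features."""

    name: str
    dim: int

    def __call__(self, tiles: np.ndarray) -> np.ndarray: ...


class SyntheticEmbedder:
    """Deterministic stand-in encoder: fixed random projection of tile summary stats.

    Each tile is reduced to a small vector of per-channel means/standard
    deviations and 2x2 quadrant means, then projected through a frozen
    Gaussian matrix. Synthetic: carries no histologic knowledge; it exists so
    the pipeline is runnable and testable without foundation-model weights.
    """

    def __init__(self, dim: int = 64, seed: int = 0):
        self.name = f"synthetic-{dim}"
        self.dim = dim
        self._rng_seed = seed
        self._proj: np.ndarray | None = None

    def _features(self, tiles: np.ndarray) -> np.ndarray:
        b = tiles.shape[0]
        t = tiles.reshape(b, -1, tiles.shape[-1]) if tiles.ndim == 4 else tiles.reshape(b, -1, 1)
        ch_mean = t.mean(axis=1)
        ch_sd = t.std(axis=1)
        h, w = tiles.shape[1], tiles.shape[2]
        quads = [
            tiles[:, : h // 2, : w // 2].reshape(b, -1).mean(axis=1),
            tiles[:, : h // 2, w // 2:].reshape(b, -1).mean(axis=1),
            tiles[:, h // 2:, : w // 2].reshape(b, -1).mean(axis=1),
            tiles[:, h // 2:, w // 2:].reshape(b, -1).mean(axis=1),
        ]
        return np.column_stack([ch_mean, ch_sd, *quads])

    def __call__(self, tiles: np.ndarray) -> np.ndarray:
        tiles = np.asarray(tiles, dtype=np.float64)
        feats = self._features(tiles)
        if self._proj is None or self._proj.shape[0] != feats.shape[1]:
            rng = np.random.default_rng(self._rng_seed)
            self._proj = rng.standard_normal((feats.shape[1], self.dim)) / np.sqrt(feats.shape[1])
        return feats @ self._proj


def extract_features(
    slide_rgb: np.ndarray,
    grid: TileGrid,
    embedder: Embedder,
    patient_id: str,
    stain_normalize: bool = True,
    batch_size: int = 64,
) -> TileBag:
    """Embed every retained tile of one slide into a :class:`TileBag`.

    Tiles that fail Macenko fitting (too little stain) are embedded
    unnormalized and logged rather than dropped.
    """
    if len(grid) == 0:
        raise ValueError(f"patient {patient_id}: empty tile grid, no bag written")
    tpx = grid.tile_px
    rows: list[np.ndarray] = []
    for start in range(0, len(grid), batch_size):
        batch = []
        for x, y in grid.coords[start:start + batch_size]:
            tile = np.asarray(slide_rgb[y:y + tpx, x:x + tpx])
            if stain_normalize:
                try:
                    tile = macenko_normalize(tile, macenko_fit(tile))
                except NotEnoughStainError:
                    logger.info("patient %s tile (%d,%d): not enough stain, kept raw", patient_id, x, y)
            batch.append(standardize_tile(tile))
        emb = np.asarray(embedder(np.stack(batch)))
        if emb.shape != (len(batch), embedder.dim):
            raise ValueError(
                f"embedder returned shape {emb.shape}, expected {(len(batch), embedder.dim)}"
            )
        if not np.isfinite(emb).all():
            raise ValueError("embedder produced non-finite values")
        rows.append(emb)
    return TileBag(
        patient_id=patient_id,
        embeddings=np.vstack(rows),
        coords=grid.coords.copy(),
        embedder_name=embedder.name,
        mpp=grid.mpp,
        tile_px=tpx,
    )


def merge_bags(bags: Sequence[TileBag]) -> TileBag:
    """Pool several slides of one patient into a single bag (patient-level labels)."""
    if not bags:
        raise ValueError("no bags to merge")
    pid = bags[0].patient_id
    if any(b.patient_id != pid for b in bags):
        raise ValueError("cannot merge bags from different patients")
    dims = {b.dim for b in bags}
    if len(dims) != 1:
        raise ValueError(f"embedding dim mismatch across slides: {sorted(dims)}")
    return TileBag(
        patient_id=pid,
        embeddings=np.vstack([b.embeddings for b in bags]),
        coords=np.vstack([b.coords for b in bags]),
        embedder_name=bags[0].embedder_name,
        mpp=bags[0].mpp,
        tile_px=bags[0].tile_px,
    )
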