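"""The MIL instance bag: per-patient tile embeddings with coordinates.

Bags are stored one patient per HDF5 file with datasets ``embeddings``
(n x d float32) and ``coords`` (n x 2 int64) and attributes ``patient_id``,
``mpp``, ``tile_px`` and ``embedder_name``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np


@dataclass
class TileBag:
    """All tile embeddings of one patient (possibly pooled over several slides)."""

    patient_id: str
    embeddings: np.ndarray  # (n_tiles, dim) float
    coords: np.ndarray      # (n_tiles, 2) int, level-0 top-left pixel positions
    embedder_name: str = "unknown"
    mpp: float = float("nan")
    tile_px: int = 0

    def __post_init__(self) -> None:
        self.embeddings = np.asarray(self.embeddings, dtype=np.float32)
        self.coords = np.asarray(self.coords, dtype=np.int64)
        if self.embeddings.ndim != 2 or self.embeddings.shape[0] < 1:
            raise ValueError("embeddings must be a non-empty (n_tiles, dim) matrix")
        if not np.isfinite(self.embeddings).all():
            raise ValueError("embeddings contain non-finite values")
        if self.coords.shape != (self.embeddings.shape[0], 2):
            raise ValueError("coords must align with embeddings (n_tiles, 2)")

    @property
    def n_tiles(self) -> int:
        return self.embeddings.shape[0]

    @property
    def dim(self) -> int:
        return self.embeddings.shape[1]

    def save(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("embeddings", data=self.embeddings.astype(np.float32))
            f.create_dataset("coords", data=self.coords.astype(np.int64))
            f.attrs["patient_id"] = self.patient_id
            f.attrs["mpp"] = self.mpp
            f.attrs["tile_px"] = self.tile_px
            f.attrs["embedder_name"] = self.embedder_name

    @classmethod
    def load(cls, path: str | Path) -> "TileBag":
        with h5py.File(path, "r") as f:
            return cls(
                patient_id=str(f.attrs["patient_id"]),
                embeddings=f["embeddings"][...],
                coords=f["coords"][...],
                embedder_name=str(f.attrs.get("embedder_name", "unknown")),
                mpp=float(f.attrs.get("mpp", float("nan"))),
                tile_px=int(f.attrs.get("tile_px", 0)),
            )


def load_bag_dir(directory: str | Path) -> dict[str, TileBag]:
    """Load every ``*.h5`` bag in a directory, keyed by patient id."""
    bags = {}
    for p in sorted(Path(directory).glob("*.h5")):
        bag = TileBag.load(p)
        bags[bag.patient_id] = bag
    return bags
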