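"""Deterministic synthetic-data generators for the full pipeline.

Real training data for this pipeline (matched whole-slide images and bulk
transcriptomics, ICI-treated cohorts with response labels) is controlled-
access and far beyond desk scale. These generators produce inputs with the
*statistical structure* each stage assumes, with planted ground truth so
parameter recovery can be verified:

* :func:`gen_bags` — tile-embedding bags with a planted low-rank linear
  signal: each patient's 30 signature values shift the mean of a fraction of
  "signal" tiles along per-signature loading directions.
* :func:`gen_cohort` — signature profiles from a Gaussian mixture (the two
  TME subtypes), responder labels from a logistic model on one planted
  pairwise interaction feature, and exponential survival times whose rate
  depends on responder status.
* :func:`gen_slide_image` — a white-background slide with elliptical tissue
  blobs rendered through a Beer–Lambert two-stain model, plus the analytic
  tissue mask.

All generators are pure functions of their spec: same spec, bit-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .bags import TileBag
from .signatures import default_registry

_DEFAULT_NAMES: tuple[str, ...] = tuple(default_registry().names)


@dataclass
class PlantedBagSpec:
    """Spec for planted-signal tile bags.

    Each patient's signature vector ``s`` is standard normal; a
    ``signal_fraction`` of that patient's tiles get their mean shifted by
    ``sum_j s_j * loading_j`` where the loadings are random orthonormal
    directions in embedding space; remaining tiles are pure isotropic noise.
    """

    n_patients: int = 200
    tiles_range: tuple[int, int] = (50, 200)
    dim: int = 64
    signal_fraction: float = 0.2
    noise_sd: float = 1.0
    signature_names: tuple[str, ...] = _DEFAULT_NAMES
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.signal_fraction <= 1):
            raise ValueError("signal_fraction must be in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def gen_bags(spec: PlantedBagSpec) -> tuple[list[TileBag], pd.DataFrame]:
    """Generate planted-signal bags and the ground-truth signature profile."""
    rng = np.random.default_rng(spec.seed)
    n_sig = len(spec.signature_names)
    if spec.dim < n_sig:
        import warnings

        warnings.warn("embedding dim < number of signatures: loading directions collide")
    # random orthonormal loading directions (dim x n_sig)
    q, _ = np.linalg.qr(rng.standard_normal((spec.dim, min(spec.dim, n_sig))))
    loadings = q[:, :n_sig] if spec.dim >= n_sig else rng.standard_normal((spec.dim, n_sig))
    s = rng.standard_normal((spec.n_patients, n_sig))
    bags = []
    lo, hi = spec.tiles_range
    for i in range(spec.n_patients):
        n_tiles = int(rng.integers(lo, hi + 1))
        x = rng.standard_normal((n_tiles, spec.dim)) * spec.noise_sd
        n_signal = max(1, int(round(spec.signal_fraction * n_tiles)))
        signal_idx = rng.choice(n_tiles, size=n_signal, replace=False)
        x[signal_idx] += loadings @ s[i]
        coords = np.column_stack([np.arange(n_tiles), np.zeros(n_tiles, dtype=int)])
        bags.append(
            TileBag(
                patient_id=f"P{i:04d}",
                embeddings=x,
                coords=coords,
                embedder_name="planted",
            )
        )
    truth = pd.DataFrame(s, index=[b.patient_id for b in bags], columns=list(spec.signature_names))
    return bags, truth


@dataclass
class PlantedCohortSpec:
    """Spec for a planted two-subtype cohort with an interaction response effect."""

    n_samples: int = 300
    separation: float = 6.0       # distance between centers, in within-cluster sd units
    within_sd: float = 1.0
    mixing: tuple[float, ...] = (0.5, 0.5)
    n_clusters: int = 2
    response_pair: tuple[str, str] = ("Coactivation_molecules", "Th2_signature")
    response_op: str = "+"
    response_slope: float = 0.0
    response_intercept: float = 0.0
    survival_rate: float = 0.1        # events per month for non-responders
    responder_rate_ratio: float = 2.0  # non-responder hazard / responder hazard
    censor_horizon: float = 60.0
    signature_names: tuple[str, ...] = _DEFAULT_NAMES
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.mixing) - 1.0) > 1e-9:
            raise ValueError("mixing weights must sum to 1")
        if self.within_sd <= 0:
            raise ValueError("within_sd must be positive")


def _planted_centers(spec: PlantedCohortSpec) -> np.ndarray:
    """Cluster centers along the antitumor-immune axis, pairwise ~`separation` apart."""
    reg = default_registry()
    names = list(spec.signature_names)
    direction = np.zeros(len(names))
    anti = [i for i, n in enumerate(names) if reg.groups.get(n) == "antitumor_immune"]
    if anti:
        direction[anti] = 1.0
    else:
        direction[: max(1, len(names) // 4)] = 1.0
    direction /= np.linalg.norm(direction)
    half = spec.separation * spec.within_sd / 2.0
    if spec.n_clusters == 2:
        return np.vstack([half * direction, -half * direction])
    rng = np.random.default_rng(spec.seed + 1)
    centers = [half * direction, -half * direction]
    # extra clusters displaced along fresh random orthogonal directions
    for _ in range(spec.n_clusters - 2):
        v = rng.standard_normal(len(names))
        v -= (v @ direction) * direction
        v /= np.linalg.norm(v)
        centers.append(spec.separation * spec.within_sd * v)
    return np.vstack(centers)


def gen_cohort(spec: PlantedCohortSpec):
    """Generate (profiles, subtype labels, clinical table).

    Returns
    -------
    profiles : DataFrame, samples x signatures.
    subtype : Series of planted mixture-component indices.
    clinical : DataFrame with columns ``responder``, ``os_time``, ``os_event``,
        ``line_of_therapy``.
    """
    rng = np.random.default_rng(spec.seed)
    names = list(spec.signature_names)
    centers = _planted_centers(spec)
    if spec.n_clusters != len(spec.mixing):
        mixing = np.full(spec.n_clusters, 1.0 / spec.n_clusters)
    else:
        mixing = np.asarray(spec.mixing)
    if np.allclose(centers, centers[0]):
        import warnings

        warnings.warn("degenerate mixture: identical cluster centers")
    comp = rng.choice(spec.n_clusters, size=spec.n_samples, p=mixing)
    profiles = centers[comp] + rng.standard_normal((spec.n_samples, len(names))) * spec.within_sd
    ids = [f"S{i:04d}" for i in range(spec.n_samples)]
    prof = pd.DataFrame(profiles, index=ids, columns=names)

    a, b = spec.response_pair
    xa, xb = prof[a].to_numpy(), prof[b].to_numpy()
    if spec.response_op == "+":
        feat = xa + xb
    elif spec.response_op == "-":
        feat = xa - xb
    elif spec.response_op == "*":
        feat = np.exp(xa) * np.exp(xb)
    elif spec.response_op == "/":
        feat = np.exp(xa) / np.exp(xb)
    else:
        raise ValueError(f"unknown response op {spec.response_op!r}")
    logit = spec.response_intercept + spec.response_slope * feat
    p_resp = 1.0 / (1.0 + np.exp(-logit))
    responder = (rng.uniform(size=spec.n_samples) < p_resp).astype(int)

    rate = np.where(responder == 1, spec.survival_rate / spec.responder_rate_ratio, spec.survival_rate)
    t_event = rng.exponential(1.0 / rate)
    t_censor = rng.uniform(0, spec.censor_horizon, size=spec.n_samples)
    os_time = np.minimum(t_event, t_censor)
    os_event = (t_event <= t_censor).astype(int)
    clinical = pd.DataFrame(
        {
            "responder": responder,
            "os_time": os_time,
            "os_event": os_event,
            "line_of_therapy": rng.choice(["first", "later"], size=spec.n_samples),
        },
        index=ids,
    )
    return prof, pd.Series(comp, index=ids, name="subtype"), clinical


def gen_slide_image(
    width: int = 2048,
    height: int = 2048,
    blobs: Sequence[tuple[float, float, float, float]] = ((0.5, 0.5, 0.3, 0.2),),
    stain_vectors: np.ndarray | None = None,
    seed: int = 0,
    mean_od: tuple[float, float] = (0.7, 0.4),
):
    """Render a synthetic H&E-like slide and its analytic tissue mask.

    ``blobs`` are ellipses ``(cx_frac, cy_frac, rx_frac, ry_frac)`` in
    relative coordinates. Inside tissue, per-pixel H and E concentrations are
    smooth positive random fields and pixels follow the Beer–Lambert law
    ``I = 256 * 10^(-(S @ c)) - 1`` for stain matrix S (3x2). Background is
    white. Returns ``(rgb_image uint8, mask bool)``.
    """
    from scipy.ndimage import gaussian_filter

    if stain_vectors is None:
        from .wsi import DEFAULT_REFERENCE_BASIS

        stain_vectors = DEFAULT_REFERENCE_BASIS
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:height, 0:width]
    mask = np.zeros((height, width), dtype=bool)
    for cx, cy, rx, ry in blobs:
        mask |= ((xx - cx * width) / (rx * width)) ** 2 + ((yy - cy * height) / (ry * height)) ** 2 <= 1.0
    conc = np.zeros((height, width, 2))
    for k in range(2):
        f = gaussian_filter(rng.standard_normal((height, width)), sigma=min(width, height) / 32)
        # wide, weakly correlated concentration ranges so some pixels approach
        # pure-H / pure-E, as in real tissue (nuclei vs cytoplasm)
        f = f / (f.std() + 1e-12) * 0.6 * mean_od[k] + mean_od[k]
        conc[..., k] = np.clip(f, 0.08, None)
    od = conc @ np.asarray(stain_vectors).T  # (h, w, 3)
    od[~mask] = 0.0
    rgb = np.clip(256.0 * np.power(10.0, -od) - 1.0, 0, 255).astype(np.uint8)
    return rgb, mask
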