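"""Seeded generator of H&E-like tiles with full instance ground truth.

Real H&E stains colour nuclei dark blue/purple (hematoxylin) and
extracellular material pink/red (eosin), so the red channel separates the
two tissue classes: extracellular pixels are bright, nuclear pixels dark.
The generator emulates exactly that contrast with per-channel Gaussian
colour noise around two class means, and draws nuclei as filled ellipses
whose long axis is centred on the 32-pixel diameter typical of cancer
nuclei in 40x material.  Deriving an *incomplete* annotation set from the
full ground truth then reproduces the partial-labelling regime the
recursive training strategy is designed for.

Not modelled: stain physics, chromatin texture, out-of-focus blur,
touching/overlapping nuclei clusters (unless ``overlap_allowed``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SynthConfig",
    "AnnotationSet",
    "PlacementError",
    "generate_image",
    "make_incomplete",
]

log = logging.getLogger(__name__)

# Green/blue class means; only the red channel enters negative mining, the
# other channels just make the tiles look plausibly H&E-like.
_NUCLEUS_GB = (0.10, 0.55)
_BACKGROUND_GB = (0.55, 0.70)


class PlacementError(RuntimeError):
    """Raised when non-overlapping nuclei cannot be placed within the retry budget."""


@dataclass
class SynthConfig:
    """Parameters of one synthetic tile.

    ``mean_long_axis`` is the mean long-axis *diameter* in pixels;
    ``axis_ratio_range`` bounds the short/long axis ratio; colour means are
    intensities in [0, 1] with the nucleus strictly darker in red than the
    background.
    """

    image_size: int = 256
    n_nuclei: int = 25
    mean_long_axis: float = 32.0
    long_axis_sd: float = 5.0
    axis_ratio_range: tuple[float, float] = (0.5, 1.0)
    nucleus_red_mean: float = 0.15
    nucleus_red_sd: float = 0.15  # per-nucleus stain heterogeneity
    background_red_mean: float = 0.85
    noise_sd: float = 0.15
    overlap_allowed: bool = False
    min_gap: int = 2  # clearance between nuclei when overlap is disallowed
    placement: str = "clustered"  # "clustered" (epithelial nests) or "uniform"
    nuclei_per_cluster: float = 8.0
    cluster_sd: float = 24.0  # spread of nuclei around a cluster centre, px
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 64:
            raise ValueError("image_size must be >= 64")
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be >= 0")
        if not (0.0 <= self.nucleus_red_mean < self.background_red_mean <= 1.0):
            raise ValueError(
                "require 0 <= nucleus_red_mean < background_red_mean <= 1"
            )
        lo, hi = self.axis_ratio_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("axis_ratio_range must satisfy 0 < lo <= hi <= 1")
        if self.placement not in ("clustered", "uniform"):
            raise ValueError("placement must be 'clustered' or 'uniform'")


@dataclass
class AnnotationSet:
    """Instance labelling of one image: 0 = background, k > 0 = nucleus k.

    ``complete`` distinguishes full ground truth from a derived incomplete
    annotation.  Labels are consecutive from 1.
    """

    labels: np.ndarray
    complete: bool
    source_image_id: str = ""

    @property
    def n_instances(self) -> int:
        return int(self.labels.max(initial=0))

    def instance_mask(self, k: int) -> np.ndarray:
        return self.labels == k

    def validate(self) -> None:
        lab = self.labels
        if lab.ndim != 2 or not np.issubdtype(lab.dtype, np.integer):
            raise ValueError("labels must be a 2-D integer raster")
        present = np.unique(lab)
        present = present[present > 0]
        if len(present) and not np.array_equal(present, np.arange(1, len(present) + 1)):
            raise ValueError("instance labels must be consecutive from 1")


def _ellipse_mask(size: int, cr: float, cc: float, a: float, b: float,
                  theta: float) -> tuple[np.ndarray, np.ndarray]:
    """Row/col indices of pixels inside the ellipse (semi-axes a >= b)."""
    r0 = max(int(np.floor(cr - a)) - 1, 0)
    r1 = min(int(np.ceil(cr + a)) + 2, size)
    c0 = max(int(np.floor(cc - a)) - 1, 0)
    c1 = min(int(np.ceil(cc + a)) + 2, size)
    rows, cols = np.mgrid[r0:r1, c0:c1]
    dy = rows - cr
    dx = cols - cc
    ct, st = np.cos(theta), np.sin(theta)
    u = (dx * ct + dy * st) / a
    v = (-dx * st + dy * ct) / b
    inside = u * u + v * v <= 1.0
    return rows[inside], cols[inside]


def generate_image(config: SynthConfig) -> tuple[np.ndarray, AnnotationSet]:
    """Generate one RGB tile in [0,1] plus its complete instance labelling.

    Nuclei are filled ellipses with randomised centre, axes and orientation;
    pixel colours are drawn around the class means with Gaussian noise and
    clipped to [0, 1].  Deterministic for a given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    size = config.image_size
    labels = np.zeros((size, size), dtype=np.int32)
    blocked = np.zeros((size, size), dtype=bool)

    # Tissue-like layout: nuclei grouped in nests around a few cluster
    # centres, leaving acellular stretches between them (what the
    # red-channel negative mining later exploits).
    clusters = None
    if config.placement == "clustered" and config.n_nuclei > 0:
        n_clusters = max(1, int(round(config.n_nuclei / config.nuclei_per_cluster)))
        m = min(config.mean_long_axis, size / 4)
        clusters = rng.uniform(m, size - m, size=(n_clusters, 2))

    placed = 0
    max_tries = 200
    for k in range(1, config.n_nuclei + 1):
        for attempt in range(max_tries):
            la = max(rng.normal(config.mean_long_axis, config.long_axis_sd), 8.0)
            a = la / 2.0
            ratio = rng.uniform(*config.axis_ratio_range)
            b = a * ratio
            margin = a + 1
            if clusters is not None and attempt < max_tries // 2:
                ctr = clusters[rng.integers(len(clusters))]
                cr = float(np.clip(ctr[0] + rng.normal(0, config.cluster_sd),
                                   margin, size - margin))
                cc = float(np.clip(ctr[1] + rng.normal(0, config.cluster_sd),
                                   margin, size - margin))
            else:  # uniform placement (also the clustered fallback)
                cr = rng.uniform(margin, size - margin)
                cc = rng.uniform(margin, size - margin)
            theta = rng.uniform(0.0, np.pi)
            rr, cc_ = _ellipse_mask(size, cr, cc, a, b, theta)
            if not config.overlap_allowed and blocked[rr, cc_].any():
                continue
            labels[rr, cc_] = k
            if not config.overlap_allowed:
                g = config.min_gap
                rrg, ccg = _ellipse_mask(size, cr, cc, a + g, b + g, theta)
                blocked[rrg, ccg] = True
            placed += 1
            break
        else:
            raise PlacementError(
                f"could not place nucleus {k}/{config.n_nuclei} after "
                f"{max_tries} attempts; reduce n_nuclei or allow overlap"
            )

    nucleus = labels > 0
    means_bg = (config.background_red_mean,) + _BACKGROUND_GB
    means_nu = (config.nucleus_red_mean,) + _NUCLEUS_GB
    # per-nucleus stain intensity: hematoxylin uptake varies between cells,
    # producing pale nuclei much closer to the eosin background
    pale_cap = config.background_red_mean - 0.20
    shifts = np.clip(
        rng.normal(0.0, config.nucleus_red_sd, size=placed),
        0.02 - config.nucleus_red_mean, pale_cap - config.nucleus_red_mean,
    )
    image = np.empty((size, size, 3), dtype=np.float32)
    for ch in range(3):
        plane = rng.normal(means_bg[ch], config.noise_sd, size=(size, size))
        for k in range(1, placed + 1):
            m = labels == k
            plane[m] = rng.normal(means_nu[ch] + shifts[k - 1],
                                  config.noise_sd, size=int(m.sum()))
        image[..., ch] = np.clip(plane, 0.0, 1.0)

    ann = AnnotationSet(labels=labels, complete=True,
                        source_image_id=f"synth-{config.seed}")
    return image, ann


def make_incomplete(annotations: AnnotationSet, fraction: float,
                    seed: int) -> AnnotationSet:
    """Keep ``round(fraction * n)`` instances, chosen uniformly without
    replacement, and relabel them consecutively.  ``fraction=1`` returns an
    identical instance set; ``fraction=0`` an empty labelling."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    n = annotations.n_instances
    keep = int(round(fraction * n))
    rng = np.random.default_rng(seed)
    chosen = np.sort(rng.choice(n, size=keep, replace=False) + 1) if keep else []
    out = np.zeros_like(annotations.labels)
    for new, old in enumerate(chosen, start=1):
        out[annotations.labels == old] = new
    return AnnotationSet(labels=out, complete=(keep == n and annotations.complete),
                         source_image_id=annotations.source_image_id)
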