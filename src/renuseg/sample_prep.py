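"""Construction of the positive and negative training patch pools.

Positive samples are 64x64 regions of interest centred at each annotated
nucleus, augmented by translating the window 16 px (a quarter of the side)
up, down, left and right — five patches per nucleus.  Target masks contain
*all annotated* nucleus pixels inside the window; unlabelled nuclei remain
background, which is precisely the annotation bias the recursive training
stage later corrects.

Negative samples come from non-cellular regions found by thresholding the
red channel at ``t = a * mean/std`` (extracellular material is brighter in
red), filling holes, removing small objects with a morphological opening,
excluding every known nucleus region with a safety margin, and randomly
cropping non-overlapping 64x64 windows from what remains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.morphology import dilation, disk, opening

from .synth import AnnotationSet

__all__ = [
    "NegativeMiningConfig",
    "PatchSet",
    "compute_negative_threshold",
    "extract_negative_regions",
    "exclude_annotated_regions",
    "crop_negative_patches",
    "extract_positive_patches",
]

log = logging.getLogger(__name__)


@dataclass
class NegativeMiningConfig:
    a: float = 0.5  # scale of the mean/std threshold
    fill_radius: int = 3  # structuring radius used around hole filling
    opening_radius: int = 20  # disk radius removing small objects
    exclusion_margin: int = 4  # dilation of known nuclei before exclusion
    patch_size: int = 64

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("a must be positive")
        if min(self.fill_radius, self.opening_radius, self.exclusion_margin) <= 0:
            raise ValueError("structuring radii must be positive")


@dataclass
class PatchSet:
    """Pool of fixed-size training patches with binary targets.

    ``polarity`` is ``"positive"`` or ``"negative"`` per patch; provenance
    records the source image, source nucleus (or ``"mined-negative"``) and
    the translation offset of the augmentation that produced the patch.
    """

    patches: np.ndarray  # (N, ps, ps, 3) float32
    targets: np.ndarray  # (N, ps, ps) bool
    polarity: np.ndarray  # (N,) str
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.patches) != len(self.targets) != len(self.polarity):
            raise ValueError("patches, targets and polarity must align")
        if np.any(self.targets[self.polarity == "negative"]):
            raise ValueError("negative targets must be all-zero")

    def __len__(self) -> int:
        return len(self.patches)

    @property
    def n_positive(self) -> int:
        return int((self.polarity == "positive").sum())

    @property
    def n_negative(self) -> int:
        return int((self.polarity == "negative").sum())

    @classmethod
    def empty(cls, patch_size: int = 64) -> "PatchSet":
        return cls(
            patches=np.zeros((0, patch_size, patch_size, 3), dtype=np.float32),
            targets=np.zeros((0, patch_size, patch_size), dtype=bool),
            polarity=np.array([], dtype=object),
        )

    @classmethod
    def concatenate(cls, sets: list["PatchSet"]) -> "PatchSet":
        sets = [s for s in sets if len(s)]
        if not sets:
            return cls.empty()
        return cls(
            patches=np.concatenate([s.patches for s in sets]),
            targets=np.concatenate([s.targets for s in sets]),
            polarity=np.concatenate([s.polarity for s in sets]),
            provenance=sum((s.provenance for s in sets), []),
        )

    # -- serialisation ------------------------------------------------------

    def save(self, path) -> None:
        """Write the pool as one ``.npz`` archive plus a CSV manifest."""
        np.savez_compressed(
            path,
            patches=self.patches,
            targets=self.targets,
            polarity=np.asarray(self.polarity, dtype=str),
        )
        pd.DataFrame(self.provenance).to_csv(str(path) + ".manifest.csv", index=False)

    @classmethod
    def load(cls, path) -> "PatchSet":
        with np.load(path) as d:
            polarity = d["polarity"].astype(object)
            out = cls(patches=d["patches"], targets=d["targets"], polarity=polarity)
        try:
            out.provenance = pd.read_csv(str(path) + ".manifest.csv").to_dict("records")
        except FileNotFoundError:
            pass
        return out


# ---------------------------------------------------------------------------
# negative mining
# ---------------------------------------------------------------------------


def compute_negative_threshold(red_channel: np.ndarray, a: float = 0.5) -> float:
    """Adaptive threshold ``t = a * mean/std`` of the red channel in [0,1]."""
    red = np.asarray(red_channel, dtype=np.float64)
    sigma = red.std()
    if sigma == 0.0:
        raise ValueError("red channel has zero standard deviation (degenerate image)")
    return float(a * red.mean() / sigma)


def extract_negative_regions(image: np.ndarray,
                             config: NegativeMiningConfig | None = None) -> np.ndarray:
    """Binary mask of candidate non-cellular (extracellular) regions.

    Pixels brighter than the adaptive red threshold are foreground; holes are
    filled and small objects removed by an opening.  May legitimately be empty
    — in particular when the threshold exceeds the intensity range, which is
    logged.
    """
    cfg = config or NegativeMiningConfig()
    red = np.asarray(image[..., 0], dtype=np.float64)
    t = compute_negative_threshold(red, cfg.a)
    if t >= red.max():
        log.warning(
            "negative-mining threshold %.3f >= max red intensity %.3f; empty mask",
            t, red.max(),
        )
        return np.zeros(red.shape, dtype=bool)
    mask = red > t
    mask = ndi.binary_fill_holes(mask)
    mask = opening(mask, disk(cfg.opening_radius))
    return mask


def exclude_annotated_regions(mask: np.ndarray,
                              exclusion: AnnotationSet | np.ndarray,
                              margin: int = 4) -> np.ndarray:
    """Remove known nucleus regions (dilated by ``margin``) from a mask.

    In synthetic mode the complete ground-truth labelling is the exclusion
    source, standing in for a manual review of the mined regions.
    """
    labels = exclusion.labels if isinstance(exclusion, AnnotationSet) else exclusion
    if labels.shape != mask.shape:
        raise ValueError("mask and exclusion rasters must share a shape")
    nuclei = labels > 0
    if margin > 0 and nuclei.any():
        nuclei = dilation(nuclei, disk(margin))
    return mask & ~nuclei


def crop_negative_patches(mask: np.ndarray, image: np.ndarray, n_max: int,
                          seed: int, patch_size: int = 64) -> PatchSet:
    """Randomly crop up to ``n_max`` non-overlapping windows inside ``mask``.

    A window qualifies only if its full footprint lies in the mask.  Returns
    fewer patches (with a logged notice) when capacity is insufficient.
    Targets are all-zero.  Deterministic given ``seed``.
    """
    h, w = mask.shape
    ps = patch_size
    if ps > min(h, w):
        raise ValueError("patch_size exceeds image side")
    # integral image -> number of mask pixels in each ps x ps window
    ii = np.pad(np.cumsum(np.cumsum(mask, axis=0), axis=1), ((1, 0), (1, 0)))
    win = ii[ps:, ps:] - ii[:-ps, ps:] - ii[ps:, :-ps] + ii[:-ps, :-ps]
    cand = np.argwhere(win == ps * ps)  # top-left corners of fully-covered windows

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(cand))
    chosen: list[tuple[int, int]] = []
    for i in order:
        r, c = map(int, cand[i])
        if any(abs(r - rr) < ps and abs(c - cc) < ps for rr, cc in chosen):
            continue
        chosen.append((r, c))
        if len(chosen) == n_max:
            break
    if len(chosen) < n_max:
        log.info("negative capacity: %d of %d requested patches", len(chosen), n_max)

    patches = np.stack(
        [image[r : r + ps, c : c + ps].astype(np.float32) for r, c in chosen]
    ) if chosen else np.zeros((0, ps, ps, 3), dtype=np.float32)
    prov = [
        {"source": "mined-negative", "row": r, "col": c, "offset": (0, 0)}
        for r, c in chosen
    ]
    return PatchSet(
        patches=patches,
        targets=np.zeros((len(chosen), ps, ps), dtype=bool),
        polarity=np.array(["negative"] * len(chosen), dtype=object),
        provenance=prov,
    )


# ---------------------------------------------------------------------------
# positive extraction
# ---------------------------------------------------------------------------

_SHIFTS = ((0, 0), (-1, 0), (1, 0), (0, -1), (0, 1))


def roi_centers(centroid: tuple[float, float], shape: tuple[int, int],
                patch_size: int = 64) -> list[tuple[int, int]]:
    """The five augmentation centres (centre plus ps/4 in each direction),
    clamped so every window stays inside the image."""
    ps = patch_size
    shift = ps // 4
    half = ps // 2
    cr = int(round(centroid[0]))
    cc = int(round(centroid[1]))
    out = []
    for dr, dc in _SHIFTS:
        r = min(max(cr + dr * shift, half), shape[0] - half)
        c = min(max(cc + dc * shift, half), shape[1] - half)
        out.append((r, c))
    return out


def extract_positive_patches(image: np.ndarray, annotations: AnnotationSet,
                             patch_size: int = 64) -> PatchSet:
    """Five augmented ROIs per annotated nucleus, with annotated-union targets.

    Always yields exactly ``5 * n_instances`` patches; each target mask is the
    union of *all* annotated nucleus pixels falling inside that window, so a
    window overlapping two annotated nuclei labels both.
    """
    n = annotations.n_instances
    if n == 0:
        raise ValueError("annotations are empty")
    ps = patch_size
    half = ps // 2
    labels = annotations.labels
    annotated = labels > 0
    patches, targets, prov = [], [], []
    for k in range(1, n + 1):
        rr, cc = np.nonzero(labels == k)
        centroid = (rr.mean(), cc.mean())
        for (r, c), (dr, dc) in zip(
            roi_centers(centroid, labels.shape, ps), _SHIFTS
        ):
            r0, c0 = r - half, c - half
            patches.append(image[r0 : r0 + ps, c0 : c0 + ps].astype(np.float32))
            targets.append(annotated[r0 : r0 + ps, c0 : c0 + ps])
            prov.append(
                {
                    "source": annotations.source_image_id,
                    "nucleus": k,
                    "offset": (dr * (ps // 4), dc * (ps // 4)),
                    "row": r0,
                    "col": c0,
                }
            )
    return PatchSet(
        patches=np.stack(patches),
        targets=np.stack(targets),
        polarity=np.array(["positive"] * len(patches), dtype=object),
        provenance=prov,
    )
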