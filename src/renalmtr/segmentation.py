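"""Semi-automatic cortex/medulla segmentation of the anatomical reference.

MT contrast alone is too flat to separate cortex from medulla, so ROIs are
drawn on a co-registered anatomical image in which the cortex is brighter
than the medulla (the medulla's longer T1 and lower oxygenation darken it on
T1/T2*-weighted references). Within an operator-supplied whole-kidney
outline the procedure is:

1. exclude the collecting system (fluid, by default *dark* on the phantom's
   reference) using its own threshold on an interior-eroded region;
2. binarize the remaining kidney pixels at an intensity threshold — brighter
   pixels become cortex, darker ones medulla;
3. morphologically open the cortex mask with a disk kernel, reassigning the
   removed pixels to medulla (cleans up isolated misclassified pixels);
4. extract the cortex-medulla border (cortex pixels 4-adjacent to medulla)
   as an auxiliary QC mask.

The threshold and kernel radius mirror the manually tuned parameters of an
interactive workflow; ``"auto"`` uses Otsu's method restricted to
within-kidney intensities. The dorsal-muscle reference ROI used for MTR
normalization is either supplied by the user (the faithful "freehand" path)
or detected automatically as the dorsal band of the image.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Union

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import dilation, disk, erosion, opening

from .errors import (
    DegenerateSegmentationWarning,
    MuscleNotFoundError,
    ValidationError,
)

# Label vocabulary shared by ground-truth and estimated label maps.
BACKGROUND = 0
CORTEX = 1
MEDULLA = 2
COLLECTING_SYSTEM = 3
MUSCLE = 4

LABEL_NAMES = {
    BACKGROUND: "background",
    CORTEX: "cortex",
    MEDULLA: "medulla",
    COLLECTING_SYSTEM: "collecting_system",
    MUSCLE: "muscle",
}

#: 4-connectivity footprint (plus-shape) used for border extraction.
_PLUS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass
class ROILabelMap:
    """Integer label arrays over the :data:`LABEL_NAMES` vocabulary.

    ``labels`` is ``(n_slices, rows, cols)`` for volumes or ``(rows, cols)``
    for a single slice. ``kidney_masks`` tags each kidney's full extent
    (cortex + medulla + collecting system) by side, which is what lets
    downstream code attribute regions to the stenotic vs contralateral
    kidney. ``border`` optionally holds the cortex-medulla border mask.
    """

    labels: np.ndarray
    kidney_masks: Dict[str, np.ndarray] = field(default_factory=dict)
    border: Optional[np.ndarray] = None


@dataclass(frozen=True)
class SegmentationParams:
    """Tunables of the semi-automatic procedure.

    threshold:
        Cortex/medulla intensity cut, or ``"auto"`` for Otsu within the
        kidney (after collecting-system exclusion).
    opening_kernel_radius:
        Disk radius (pixels) of the morphological opening applied to the
        cortex mask; 0 disables the step.
    collecting_system_threshold:
        Intensity cut for the collecting system, or ``"auto"`` (Otsu within
        the sub-threshold kidney pixels, guarded by a bimodality check).
    collecting_dark:
        Whether collecting-system fluid is darker (default) or brighter than
        parenchyma on the reference image.
    interior_erosion:
        Erosion radius defining the kidney interior in which the collecting
        system may be excluded (keeps the cortical rim out of step 1).
    """

    threshold: Union[float, str] = "auto"
    opening_kernel_radius: int = 2
    collecting_system_threshold: Union[float, str] = "auto"
    collecting_dark: bool = True
    interior_erosion: int = 2

    def __post_init__(self) -> None:
        if self.opening_kernel_radius < 0:
            raise ValidationError("opening_kernel_radius must be >= 0")
        if self.interior_erosion < 0:
            raise ValidationError("interior_erosion must be >= 0")
        for name in ("threshold", "collecting_system_threshold"):
            v = getattr(self, name)
            if isinstance(v, str):
                if v != "auto":
                    raise ValidationError(f"{name} must be numeric or 'auto'")
            elif not np.isfinite(v):
                raise ValidationError(f"{name} must be finite")


def _auto_collecting_threshold(values: np.ndarray) -> Optional[float]:
    """Otsu split of the darker kidney compartment, with a bimodality guard.

    Returns None when the sub-population does not separate into two clearly
    distinct modes (then no collecting system is excluded).
    """
    if values.size < 8 or np.ptp(values) == 0:
        return None
    t = float(threshold_otsu(values))
    lo, hi = values[values < t], values[values >= t]
    if lo.size == 0 or hi.size == 0:
        return None
    gap = float(hi.mean() - lo.mean())
    spread = float(np.std(lo) + np.std(hi))
    if gap <= 2.0 * spread:  # unimodal: Otsu is just splitting noise
        return None
    return t


def segment_kidney(
    anatomical_slice: np.ndarray,
    kidney_mask: np.ndarray,
    params: SegmentationParams = SegmentationParams(),
) -> ROILabelMap:
    """Segment one kidney on one anatomical slice.

    Returns an :class:`ROILabelMap` whose 2-D ``labels`` are nonzero only
    inside ``kidney_mask`` and whose ``border`` holds the cortex-medulla
    border mask. If the threshold separates nothing, a
    :class:`DegenerateSegmentationWarning` is issued and all parenchymal
    pixels are assigned to the single (majority) class.
    """
    img = np.asarray(anatomical_slice, dtype=float)
    mask = np.asarray(kidney_mask, dtype=bool)
    if img.shape != mask.shape or img.ndim != 2:
        raise ValidationError("anatomical slice and kidney mask must be matching 2-D")
    if not mask.any():
        raise ValidationError("kidney mask is empty")
    if not np.all(np.isfinite(img[mask])):
        raise ValidationError("anatomical intensities must be finite")

    labels = np.zeros(img.shape, dtype=np.int16)

    # (1) collecting-system exclusion on the interior-eroded mask
    interior = (
        erosion(mask, disk(params.interior_erosion))
        if params.interior_erosion > 0
        else mask
    )
    collecting = np.zeros_like(mask)
    cs_thr = params.collecting_system_threshold
    vals = img[mask]
    if cs_thr == "auto":
        main_thr = float(threshold_otsu(vals)) if np.ptp(vals) > 0 else None
        if main_thr is not None:
            sub = vals[vals < main_thr] if params.collecting_dark else vals[vals >= main_thr]
            t = _auto_collecting_threshold(sub)
            if t is not None:
                collecting = (
                    (img < t) if params.collecting_dark else (img >= t)
                ) & interior
    else:
        collecting = (
            (img < cs_thr) if params.collecting_dark else (img >= cs_thr)
        ) & interior
    labels[collecting] = COLLECTING_SYSTEM

    # (2) binarize the parenchyma: bright -> cortex, dark -> medulla
    parenchyma = mask & ~collecting
    pvals = img[parenchyma]
    if np.ptp(pvals) == 0:
        thr = np.inf  # forces the degenerate branch below
    elif params.threshold == "auto":
        thr = float(threshold_otsu(pvals))
    else:
        thr = float(params.threshold)
    cortex = parenchyma & (img >= thr)
    medulla = parenchyma & ~cortex

    if not cortex.any() or not medulla.any():
        warnings.warn(
            "threshold separated nothing within the kidney; assigning all "
            "parenchymal pixels to a single class",
            DegenerateSegmentationWarning,
            stacklevel=2,
        )
        majority = CORTEX if cortex.sum() >= medulla.sum() else MEDULLA
        labels[parenchyma] = majority
        return ROILabelMap(labels=labels, border=np.zeros_like(mask))

    # (3) opening of the cortex mask; removed pixels go to medulla
    if params.opening_kernel_radius > 0:
        opened = opening(cortex, disk(params.opening_kernel_radius))
        medulla = medulla | (cortex & ~opened)
        cortex = opened
    labels[cortex] = CORTEX
    labels[medulla] = MEDULLA

    # (4) cortex-medulla border (cortex pixels 4-adjacent to medulla)
    border = cortex & dilation(medulla, _PLUS)
    return ROILabelMap(labels=labels, border=border)


def segment_muscle(
    anatomical_slice: np.ndarray,
    params: SegmentationParams = SegmentationParams(),
    user_mask: Optional[np.ndarray] = None,
    background_fraction: float = 0.3,
    dorsal_fraction: float = 0.7,
) -> np.ndarray:
    """Return the dorsal-muscle reference ROI for one slice.

    A user-supplied mask (the freehand-ROI path) is returned verbatim.
    Otherwise the dorsal band is detected as the largest foreground
    connected component whose centroid lies in the dorsal (bottom)
    ``1 - dorsal_fraction`` of the image, eroded by 1 px to avoid edge
    partial-volume pixels.
    """
    img = np.asarray(anatomical_slice, dtype=float)
    if user_mask is not None:
        user_mask = np.asarray(user_mask, dtype=bool)
        if user_mask.shape != img.shape:
            raise ValidationError("user muscle mask shape mismatch")
        return user_mask
    robust_max = float(np.percentile(img, 99))
    if robust_max <= 0:
        raise MuscleNotFoundError(
            "no dorsal muscle found automatically; supply a manual muscle ROI"
        )
    fg = img > background_fraction * robust_max
    comps, n = cc_label(fg, connectivity=2, return_num=True)
    best: Optional[np.ndarray] = None
    for i in range(1, n + 1):
        comp = comps == i
        rows = np.nonzero(comp)[0]
        if rows.mean() >= dorsal_fraction * img.shape[0]:
            if best is None or comp.sum() > best.sum():
                best = comp
    if best is None:
        raise MuscleNotFoundError(
            "no dorsal muscle found automatically; supply a manual muscle ROI"
        )
    eroded = ndimage.binary_erosion(best, structure=np.ones((3, 3)))
    if not eroded.any():
        raise MuscleNotFoundError(
            "detected dorsal band too thin; supply a manual muscle ROI"
        )
    return eroded


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap ``2|A∩B| / (|A| + |B|)``; two empty masks give 1.0."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValidationError(f"shape mismatch: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom
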