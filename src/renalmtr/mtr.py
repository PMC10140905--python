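"""Pixel-wise magnetization-transfer-ratio (MTR) maps.

The MTR quantifies the fractional signal loss caused by an off-resonance
saturation pulse,

    MTR = (M0 - MT) / M0,

where ``M0`` is the image acquired without MT preparation and ``MT`` the
MT-weighted image. Higher MTR indicates a larger macromolecular (e.g.
collagen) pool, which is why it is used as a surrogate marker of fibrosis.

Air/background pixels have near-zero M0 and would blow up the ratio, so the
map carries a validity mask: pixels are valid only where M0 exceeds a small
fraction of the robust image maximum and where the computed ratio is
physically plausible. Valid MTR values are deliberately *not* clipped to
[0, 1] — at low SNR, noise can push a true small MTR slightly negative, and
clipping would bias downstream ROI means. Values in [-0.5, 0) are retained;
anything outside [-0.5, 1] is treated as non-physical and masked out.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import TYPE_CHECKING, Optional

import numpy as np

from .errors import EmptyMaskWarning, ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .phantom import AcquisitionMeta

#: Fraction of the robust (99th percentile) M0 maximum below which a pixel
#: is considered background.
DEFAULT_BACKGROUND_THRESHOLD = 0.05

#: Plausibility window for noisy MTR values; outside it pixels are invalid.
MTR_VALID_RANGE = (-0.5, 1.0)


@dataclass(frozen=True)
class MTImageSet:
    """Paired M0 / MT-weighted slice stacks from one acquisition.

    Arrays are ``(n_slices, rows, cols)`` with non-negative magnitude
    intensities in arbitrary units.
    """

    m0: np.ndarray
    mt: np.ndarray
    meta: Optional["AcquisitionMeta"] = None

    def __post_init__(self) -> None:
        m0 = np.asarray(self.m0, dtype=float)
        mt = np.asarray(self.mt, dtype=float)
        if m0.shape != mt.shape:
            raise ValidationError(
                f"M0 shape {m0.shape} does not match MT shape {mt.shape}"
            )
        if m0.ndim != 3:
            raise ValidationError("image stacks must be 3-D (slices, rows, cols)")
        if np.any(m0 < 0) or np.any(mt < 0):
            raise ValidationError("magnitude intensities must be non-negative")
        object.__setattr__(self, "m0", m0)
        object.__setattr__(self, "mt", mt)

    @property
    def n_slices(self) -> int:
        return self.m0.shape[0]


@dataclass(frozen=True)
class MTRMap:
    """Per-slice MTR arrays with a validity mask.

    ``mtr`` is NaN wherever ``valid_mask`` is False; consumers must average
    over valid pixels only.
    """

    mtr: np.ndarray
    valid_mask: np.ndarray
    meta: Optional["AcquisitionMeta"] = None

    @property
    def n_slices(self) -> int:
        return self.mtr.shape[0]


def compute_mtr_map(
    images: MTImageSet,
    background_threshold: float = DEFAULT_BACKGROUND_THRESHOLD,
) -> MTRMap:
    """Compute the pixel-wise MTR map ``(M0 - MT)/M0`` with masking.

    Parameters
    ----------
    images
        Paired M0 / MT stacks.
    background_threshold
        Fraction of the robust M0 maximum (99th percentile over the whole
        stack) below which pixels are masked as background. Must lie in
        ``[0, 1)``.

    Returns
    -------
    MTRMap
        MTR is defined (non-NaN) exactly where ``valid_mask`` is True.
    """
    if not 0 <= background_threshold < 1:
        raise ValidationError("background_threshold must lie in [0, 1)")
    m0, mt = images.m0, images.mt
    robust_max = float(np.percentile(m0, 99))
    valid = m0 > background_threshold * robust_max
    if robust_max == 0 or not valid.any():
        warnings.warn(
            "M0 stack has no pixels above the background threshold; "
            "MTR map is empty",
            EmptyMaskWarning,
            stacklevel=2,
        )
        valid = np.zeros_like(valid)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (m0 - mt) / m0
    lo, hi = MTR_VALID_RANGE
    valid = valid & np.isfinite(ratio) & (ratio >= lo) & (ratio <= hi)
    mtr = np.where(valid, ratio, np.nan)
    return MTRMap(mtr=mtr, valid_mask=valid, meta=images.meta)
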