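"""Regional MTR statistics: ROI means and muscle normalization.

Kidney regional MTR is normalized by the dorsal-muscle MTR of the *same
slice* to adjust for intra- and inter-subject B1 inhomogeneity: a
multiplicative saturation-efficiency scale common to kidney and muscle
cancels exactly in the ratio. Normalization is applied per slice first and
the normalized values are then averaged (unweighted) across slices; sham
subjects' two normal kidneys are averaged into a single per-subject value
per region so group sizes match animal counts (n = 6 normal, 9 STK, 9 CLK).
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import pandas as pd

from .errors import EmptyRegionError, ValidationError
from .mtr import MTRMap

logger = logging.getLogger(__name__)

#: Fixed column order of the tidy per-acquisition summary table.
SUMMARY_COLUMNS = [
    "subject",
    "group",
    "role",
    "region",
    "field_T",
    "offset_hz",
    "timepoint",
    "raw_mtr",
    "muscle_mtr",
    "norm_mtr",
]

MEASUREMENT_COLUMNS = [
    "subject",
    "group",
    "side",
    "role",
    "region",
    "slice",
    "field_T",
    "offset_hz",
    "timepoint",
    "raw_mtr",
    "muscle_mtr",
    "norm_mtr",
]


def region_mean_mtr(
    mtr_map: MTRMap,
    region_mask: np.ndarray,
    slice_index: Optional[int] = None,
    region_name: str = "region",
) -> float:
    """Arithmetic mean of the MTR over ``region_mask`` ∩ valid pixels.

    ``region_mask`` may be a 2-D mask for one slice (give ``slice_index``)
    or a full-stack 3-D mask.
    """
    if slice_index is not None:
        mtr = mtr_map.mtr[slice_index]
        valid = mtr_map.valid_mask[slice_index]
    else:
        mtr, valid = mtr_map.mtr, mtr_map.valid_mask
    mask = np.asarray(region_mask, dtype=bool)
    if mask.shape != mtr.shape:
        raise ValidationError(f"region mask shape {mask.shape} != MTR shape {mtr.shape}")
    sel = mask & valid
    if not sel.any():
        where = "" if slice_index is None else f" on slice {slice_index}"
        raise EmptyRegionError(f"no valid MTR pixels in {region_name}{where}")
    return float(mtr[sel].mean())


def normalize_by_muscle(region_mtr: float, muscle_mtr: float) -> float:
    """Muscle-normalized MTR: ``region_mtr / muscle_mtr``."""
    if not muscle_mtr > 0:
        raise ValidationError(f"muscle MTR must be > 0, got {muscle_mtr}")
    return region_mtr / muscle_mtr


def measure_regions(
    mtr_map: MTRMap,
    region_masks: dict,
    muscle_mask_by_slice,
    context: Optional[dict] = None,
) -> pd.DataFrame:
    """Per-slice raw and muscle-normalized regional MTR means.

    Parameters
    ----------
    region_masks
        ``{(side, region): 3-D bool mask}`` over the MTR stack.
    muscle_mask_by_slice
        Sequence of 2-D muscle masks (or None where the muscle ROI is
        unavailable; those slices are logged and skipped).
    context
        Constant columns (subject, group, role-per-side, meta ...) merged
        into every row.

    Slices where a region or the muscle has no valid pixels are logged and
    skipped; at least one surviving slice per region is required downstream.
    """
    context = context or {}
    roles = context.get("roles", {})
    rows = []
    for s in range(mtr_map.n_slices):
        muscle_mask = muscle_mask_by_slice[s]
        if muscle_mask is None:
            logger.warning("slice %d: no muscle ROI; skipping slice", s)
            continue
        try:
            muscle = region_mean_mtr(mtr_map, muscle_mask, s, "muscle")
        except EmptyRegionError as exc:
            logger.warning("slice %d: %s; skipping slice", s, exc)
            continue
        for (side, region), mask in region_masks.items():
            try:
                raw = region_mean_mtr(mtr_map, mask[s], s, f"{side} {region}")
            except EmptyRegionError as exc:
                logger.warning("slice %d: %s; skipping region", s, exc)
                continue
            rows.append(
                dict(
                    subject=context.get("subject"),
                    group=context.get("group"),
                    side=side,
                    role=roles.get(side),
                    region=region,
                    slice=s,
                    field_T=context.get("field_T"),
                    offset_hz=context.get("offset_hz"),
                    timepoint=context.get("timepoint"),
                    raw_mtr=raw,
                    muscle_mtr=muscle,
                    norm_mtr=normalize_by_muscle(raw, muscle),
                )
            )
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)


def summarize_subjects(measurements: pd.DataFrame) -> pd.DataFrame:
    """Collapse per-slice measurements to one value per subject/role/region.

    Per kidney: unweighted mean across the slices that produced a valid
    measurement (per-slice normalization already applied). Per subject: the
    two kidneys of a sham animal share the role "normal" and are averaged
    into a single value, so the unit of analysis is the animal.
    """
    if measurements.empty:
        raise ValidationError("no measurements to summarize")
    strata = ["field_T", "offset_hz", "timepoint"]
    per_kidney = (
        measurements.groupby(
            ["subject", "group", "side", "role", "region"] + strata, sort=True
        )[["raw_mtr", "muscle_mtr", "norm_mtr"]]
        .mean()
        .reset_index()
    )
    per_subject = (
        per_kidney.groupby(["subject", "group", "role", "region"] + strata, sort=True)[
            ["raw_mtr", "muscle_mtr", "norm_mtr"]
        ]
        .mean()
        .reset_index()
    )
    return per_subject[SUMMARY_COLUMNS]
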