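"""End-to-end orchestration: simulate/ingest -> MTR -> segment -> summarize -> stats.

`run_pipeline` executes the stages on a configuration, writes tidy CSV
tables, a text report and a JSON manifest (versions, seed, parameters)
sufficient to reproduce the outputs byte-identically, and optionally QC
PNGs (MTR map with ROI overlay per acquisition). `measure_dataset` is the
in-memory core used by both the pipeline and programmatic callers.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .errors import MuscleNotFoundError, PipelineError, ValidationError
from .mtr import DEFAULT_BACKGROUND_THRESHOLD, MTRMap, compute_mtr_map
from .phantom import (
    AcquisitionRecord,
    CohortSpec,
    PhantomDataset,
    REGIONS,
    SubjectRecord,
    generate_cohort,
)
from .regional import measure_regions, summarize_subjects
from .segmentation import (
    CORTEX,
    MEDULLA,
    MUSCLE,
    ROILabelMap,
    SegmentationParams,
    segment_kidney,
    segment_muscle,
)
from .stats import ComparisonResult, format_report, results_to_frame, run_comparison_grid

logger = logging.getLogger(__name__)

_CSV_FLOAT_FORMAT = "%.12g"  # fixed text precision for byte-stable outputs


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one pipeline run."""

    out_dir: Path
    seed: int = 0
    cohort: CohortSpec = dc_field(default_factory=CohortSpec)
    input_dir: Optional[Path] = None  # ingest real/written data instead of simulating
    seg_params: SegmentationParams = dc_field(default_factory=SegmentationParams)
    background_threshold: float = DEFAULT_BACKGROUND_THRESHOLD
    labels_source: str = "estimated"  # "estimated" | "truth"
    grids: Sequence[str] = ("groups", "fields", "timepoints")
    holm: bool = False
    write_nifti: bool = False
    qc: bool = False

    def __post_init__(self) -> None:
        if self.labels_source not in ("estimated", "truth"):
            raise ValidationError("labels_source must be 'estimated' or 'truth'")


@dataclass
class PipelineResult:
    measurements: pd.DataFrame
    summary: pd.DataFrame
    comparisons: List[ComparisonResult]
    out_dir: Optional[Path] = None


def _estimated_masks(
    record: AcquisitionRecord,
    geometry: ROILabelMap,
    params: SegmentationParams,
    acq_id: str,
) -> Tuple[Dict, List[Optional[np.ndarray]], np.ndarray]:
    """Segment every slice; returns region masks, muscle masks, label stack."""
    if record.anatomical is None:
        raise PipelineError(
            f"stage 'segmentation' failed for acquisition '{acq_id}': "
            "anatomical volume missing"
        )
    n_slices = record.images.n_slices
    shape = record.images.m0.shape
    est_labels = np.zeros(shape, dtype=np.int16)
    region_masks = {
        (side, region): np.zeros(shape, dtype=bool)
        for side in geometry.kidney_masks
        for region in REGIONS
    }
    muscle_by_slice: List[Optional[np.ndarray]] = []
    for s in range(n_slices):
        anat = record.anatomical[s]
        for side, kmask in geometry.kidney_masks.items():
            seg = segment_kidney(anat, kmask[s], params)
            region_masks[(side, "cortex")][s] = seg.labels == CORTEX
            region_masks[(side, "medulla")][s] = seg.labels == MEDULLA
            est_labels[s][seg.labels > 0] = seg.labels[seg.labels > 0]
        if record.user_muscle is not None:
            muscle = record.user_muscle[s]
        else:
            try:
                muscle = segment_muscle(anat, params)
            except MuscleNotFoundError as exc:
                logger.warning("%s slice %d: %s", acq_id, s, exc)
                muscle = None
        if muscle is not None:
            est_labels[s][muscle] = MUSCLE
        muscle_by_slice.append(muscle)
    return region_masks, muscle_by_slice, est_labels


def _truth_masks(geometry: ROILabelMap) -> Tuple[Dict, List[np.ndarray]]:
    lab = geometry.labels
    region_masks = {}
    for side, kmask in geometry.kidney_masks.items():
        region_masks[(side, "cortex")] = (lab == CORTEX) & kmask
        region_masks[(side, "medulla")] = (lab == MEDULLA) & kmask
    muscle_by_slice = [lab[s] == MUSCLE for s in range(lab.shape[0])]
    return region_masks, muscle_by_slice


def analyze_acquisition(
    subject: SubjectRecord,
    record: AcquisitionRecord,
    seg_params: SegmentationParams,
    background_threshold: float,
    labels_source: str = "estimated",
) -> Tuple[pd.DataFrame, MTRMap, Optional[np.ndarray]]:
    """MTR map + segmentation + regional measurement for one acquisition."""
    meta = record.meta
    acq_id = f"{subject.subject_id}/{meta.field_strength:g}T_{meta.offset_frequency}Hz_tp{meta.timepoint}"
    mtr_map = compute_mtr_map(record.images, background_threshold)
    if labels_source == "truth":
        region_masks, muscle_by_slice = _truth_masks(subject.geometry)
        est_labels = None
    else:
        region_masks, muscle_by_slice, est_labels = _estimated_masks(
            record, subject.geometry, seg_params, acq_id
        )
    context = dict(
        subject=subject.subject_id,
        group=subject.group,
        roles=subject.roles,
        field_T=meta.field_strength,
        offset_hz=meta.offset_frequency,
        timepoint=meta.timepoint,
    )
    df = measure_regions(mtr_map, region_masks, muscle_by_slice, context)
    return df, mtr_map, est_labels


def measure_dataset(
    dataset: PhantomDataset,
    seg_params: Optional[SegmentationParams] = None,
    background_threshold: float = DEFAULT_BACKGROUND_THRESHOLD,
    labels_source: str = "estimated",
) -> pd.DataFrame:
    """Tidy per-slice measurement table for a whole cohort."""
    seg_params = seg_params or SegmentationParams()
    frames = []
    for subj in dataset.subjects:
        for key in sorted(subj.acquisitions):
            record = subj.acquisitions[key]
            df, _, _ = analyze_acquisition(
                subj, record, seg_params, background_threshold, labels_source
            )
            frames.append(df)
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    if out.empty:
        raise ValidationError("dataset produced no measurements")
    return out


def _qc_png(
    path: Path,
    record: AcquisitionRecord,
    mtr_map: MTRMap,
    est_labels: Optional[np.ndarray],
) -> None:
    """MTR map + ROI-overlay QC figure (mid slice)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    s = record.images.n_slices // 2
    fig, axes = plt.subplots(1, 3, figsize=(9, 3))
    axes[0].imshow(record.images.m0[s], cmap="gray")
    axes[0].set_title("M0")
    axes[1].imshow(mtr_map.mtr[s], cmap="magma", vmin=0, vmax=0.5)
    axes[1].set_title("MTR")
    axes[2].imshow(record.images.m0[s], cmap="gray")
    if est_labels is not None:
        masked = np.ma.masked_equal(est_labels[s], 0)
        axes[2].imshow(masked, cmap="tab10", alpha=0.5, vmin=0, vmax=9)
    axes[2].set_title("ROIs")
    for ax in axes:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=80)
    plt.close(fig)


def _config_manifest(config: PipelineConfig) -> dict:
    def clean(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: clean(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, dict):
            return {str(k): clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [clean(v) for v in obj]
        if isinstance(obj, Path):
            return str(obj)
        return obj

    return clean(config)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full pipeline and write the result bundle.

    Any stage failure aborts with a :class:`PipelineError` naming the stage
    (and, where applicable, the offending acquisition).
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    # --- stage 1: simulate or ingest -------------------------------------
    try:
        if config.input_dir is not None:
            from .io import read_dataset

            dataset = read_dataset(Path(config.input_dir))
        else:
            dataset = generate_cohort(config.cohort, config.seed)
    except PipelineError:
        raise
    except Exception as exc:
        stage = "ingest" if config.input_dir is not None else "simulate"
        raise PipelineError(f"stage '{stage}' failed: {exc}") from exc

    if config.write_nifti and config.input_dir is None:
        from .io import write_dataset

        write_dataset(dataset, out_dir / "nifti")

    # --- stages 2-3: mtr + segmentation + regional measurement -----------
    qc_dir = out_dir / "qc"
    if config.qc:
        qc_dir.mkdir(exist_ok=True)
    frames = []
    for subj in dataset.subjects:
        for key in sorted(subj.acquisitions):
            record = subj.acquisitions[key]
            meta = record.meta
            acq_id = (
                f"{subj.subject_id}/{meta.field_strength:g}T_"
                f"{meta.offset_frequency}Hz_tp{meta.timepoint}"
            )
            try:
                df, mtr_map, est_labels = analyze_acquisition(
                    subj,
                    record,
                    config.seg_params,
                    config.background_threshold,
                    config.labels_source,
                )
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(
                    f"stage 'analyze' failed for acquisition '{acq_id}': {exc}"
                ) from exc
            frames.append(df)
            if config.qc:
                _qc_png(
                    qc_dir / (acq_id.replace("/", "_") + ".png"),
                    record,
                    mtr_map,
                    est_labels,
                )
    measurements = pd.concat(frames, ignore_index=True)

    # --- stage 4: subject summaries ---------------------------------------
    try:
        summary = summarize_subjects(measurements)
    except Exception as exc:
        raise PipelineError(f"stage 'summarize' failed: {exc}") from exc

    # --- stage 5: statistics ----------------------------------------------
    try:
        comparisons = run_comparison_grid(summary, grids=config.grids, holm=config.holm)
    except Exception as exc:
        raise PipelineError(f"stage 'stats' failed: {exc}") from exc

    # --- outputs ----------------------------------------------------------
    measurements.to_csv(
        out_dir / "measurements.csv", index=False, float_format=_CSV_FLOAT_FORMAT
    )
    summary.to_csv(out_dir / "summary.csv", index=False, float_format=_CSV_FLOAT_FORMAT)
    results_to_frame(comparisons).to_csv(
        out_dir / "stats.csv", index=False, float_format=_CSV_FLOAT_FORMAT
    )
    (out_dir / "report.txt").write_text(format_report(comparisons))

    import scipy
    import skimage

    manifest = dict(
        renalmtr=__version__,
        numpy=np.__version__,
        scipy=scipy.__version__,
        pandas=pd.__version__,
        scikit_image=skimage.__version__,
        seed=config.seed,
        config=_config_manifest(config),
        outputs=["measurements.csv", "summary.csv", "stats.csv", "report.txt"],
    )
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))

    return PipelineResult(
        measurements=measurements,
        summary=summary,
        comparisons=comparisons,
        out_dir=out_dir,
    )
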