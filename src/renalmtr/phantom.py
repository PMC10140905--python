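"""Digital phantom: synthetic MT-weighted renal cohorts with ground truth.

The generator emulates a two-arm porcine study — subjects with unilateral
renal artery stenosis (RAS), carrying one stenotic (STK) and one
contralateral (CLK) kidney, and sham controls with two normal kidneys —
imaged at two field strengths (1.5 T, 3 T), two MT offset frequencies
(600, 1000 Hz) and two timepoints, five coronal slices per acquisition.

Forward model
-------------
Tissue contrast is parameterized directly by the observed true MTR of each
tissue class (no two-pool Bloch-McConnell simulation): the noiseless MT
channel is

    MT(x) = M0(x) * (1 - s(x) * MTR_true(class(x))),

so that (M0 - MT)/M0 recovers ``s * MTR_true`` exactly. ``s(x)`` is a
multiplicative B1 saturation-efficiency field (smooth low-order 2-D
polynomial, |s - 1| <= amplitude) acting on the MT channel only; Rician
magnitude noise of standard deviation ``M0_tissue / SNR`` is applied
independently to both channels and to the anatomical reference.

Kidney true MTRs default to (normalized tissue MTR) x (muscle true MTR),
with normalized means/SDs per field-offset stratum taken from the study's
group table, so that muscle-normalized estimates are directly comparable to
those published values. Between-subject biology enters as Gaussian jitter
on the normalized truths (one draw per subject, kidney, field and offset,
shared across timepoints); a configurable decrement at timepoint 2 emulates
the MTR fall seen in maturing normal kidneys.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field as dc_field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import GeometryError, ValidationError
from .mtr import MTImageSet
from .segmentation import (
    BACKGROUND,
    COLLECTING_SYSTEM,
    CORTEX,
    MEDULLA,
    MUSCLE,
    ROILabelMap,
)

SIDES = ("left", "right")
REGIONS = ("cortex", "medulla")
ROLES = ("normal", "stenotic", "contralateral")

#: Published group means and SDs of muscle-normalized MTR per
#: (field_T, offset_Hz) stratum, region and kidney role. These parameterize
#: the phantom's default tissue truths.
TABLE1_NORMALIZED_MTR: Dict[Tuple[float, int], Dict[str, Dict[str, Tuple[float, float]]]] = {
    (3.0, 600): {
        "cortex": {"normal": (0.68, 0.04), "stenotic": (0.75, 0.08), "contralateral": (0.64, 0.08)},
        "medulla": {"normal": (0.64, 0.04), "stenotic": (0.74, 0.04), "contralateral": (0.53, 0.15)},
    },
    (1.5, 600): {
        "cortex": {"normal": (0.69, 0.13), "stenotic": (0.71, 0.04), "contralateral": (0.69, 0.07)},
        "medulla": {"normal": (0.61, 0.17), "stenotic": (0.67, 0.12), "contralateral": (0.52, 0.17)},
    },
    (3.0, 1000): {
        "cortex": {"normal": (0.65, 0.13), "stenotic": (0.70, 0.10), "contralateral": (0.61, 0.10)},
        "medulla": {"normal": (0.61, 0.09), "stenotic": (0.68, 0.06), "contralateral": (0.50, 0.17)},
    },
    (1.5, 1000): {
        "cortex": {"normal": (0.60, 0.05), "stenotic": (0.67, 0.04), "contralateral": (0.66, 0.07)},
        "medulla": {"normal": (0.52, 0.08), "stenotic": (0.62, 0.11), "contralateral": (0.50, 0.16)},
    },
}

DEFAULT_ANATOMICAL_INTENSITY = {
    "background": 0.0,
    "cortex": 1.0,
    "medulla": 0.55,
    "collecting_system": 0.15,
    "muscle": 0.80,
}

_NORM_TRUTH_CLIP = (0.05, 2.2)  # keeps kidney true MTR inside [0, 1)


@dataclass(frozen=True)
class AcquisitionMeta:
    """Acquisition metadata carried verbatim through the pipeline."""

    field_strength: float
    offset_frequency: int
    timepoint: int = 1
    matrix_size: int = 128
    n_slices: int = 5
    pixel_spacing_mm: float = 2.34  # 30 cm FOV / 128

    def __post_init__(self) -> None:
        if self.field_strength not in (1.5, 3.0):
            raise ValidationError("field_strength must be 1.5 or 3.0 T")
        if self.offset_frequency not in (600, 1000):
            raise ValidationError("offset_frequency must be 600 or 1000 Hz")
        if self.timepoint not in (1, 2):
            raise ValidationError("timepoint must be 1 or 2")
        if self.n_slices < 1:
            raise ValidationError("n_slices must be >= 1")


@dataclass(frozen=True)
class B1FieldSpec:
    """Multiplicative saturation-efficiency field model.

    The realized field is ``1 + amplitude * g(x, y)`` with ``g`` a random
    polynomial of the given order normalized to ``max |g| = 1``, so
    ``|s - 1| <= amplitude`` everywhere. Coefficient scales are
    constant-dominant (transmit-gain miscalibration dominates inter-subject
    B1 variation), which is the component muscle normalization cancels.
    """

    amplitude: float = 0.05
    order: int = 2

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValidationError("B1 amplitude must be >= 0")
        if self.order < 0:
            raise ValidationError("B1 polynomial order must be >= 0")


@dataclass(frozen=True)
class NoiseSpec:
    """Rician magnitude-noise level: sigma = (M0 tissue signal) / snr."""

    snr: float = 40.0

    def __post_init__(self) -> None:
        if not self.snr > 0:
            raise ValidationError("snr must be > 0 (use math.inf for noiseless)")


@dataclass(frozen=True)
class TissueTruth:
    """True tissue MTRs and anatomical intensities for one acquisition.

    ``kidney_mtr`` maps kidney side -> region -> true (absolute) MTR; sides
    are used rather than roles because sham subjects carry two independent
    normal kidneys. All true MTRs are dimensionless fractions in [0, 1);
    background is implicitly 0.
    """

    kidney_mtr: Mapping[str, Mapping[str, float]]
    muscle_mtr: float = 0.40
    collecting_mtr: float = 0.10
    anatomical_intensity: Mapping[str, float] = dc_field(
        default_factory=lambda: dict(DEFAULT_ANATOMICAL_INTENSITY)
    )

    def __post_init__(self) -> None:
        values = [self.muscle_mtr, self.collecting_mtr] + [
            v for side in self.kidney_mtr.values() for v in side.values()
        ]
        for v in values:
            if not 0 <= v < 1:
                raise ValidationError(f"true MTR {v} outside [0, 1)")
        if not self.muscle_mtr > 0:
            raise ValidationError("muscle true MTR must be > 0")
        ai = self.anatomical_intensity
        if ai["cortex"] <= ai["medulla"]:
            raise ValidationError(
                "cortex anatomical intensity must exceed medulla (segmentation contrast)"
            )


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def _slice_scales(n_slices: int) -> np.ndarray:
    """Through-plane shrink of kidney cross-sections toward the poles."""
    if n_slices == 1:
        return np.ones(1)
    c = (n_slices - 1) / 2.0
    i = np.arange(n_slices)
    return 1.0 - 0.15 * ((i - c) / c) ** 2


def _ellipse(shape: Tuple[int, int], cr: float, cc: float, ar: float, ac: float) -> np.ndarray:
    rr, col = np.ogrid[: shape[0], : shape[1]]
    return ((rr - cr) / ar) ** 2 + ((col - cc) / ac) ** 2 <= 1.0


#: Inner-ellipse axis fractions: medulla within cortex, collecting system core.
MEDULLA_SCALE = 0.62
COLLECTING_SCALE = 0.28


def build_geometry(meta: AcquisitionMeta, seed) -> ROILabelMap:
    """Place two elliptical-annulus kidneys and a dorsal muscle band.

    Each kidney is a cortical rim (>= 2 px thick) around a medullary
    interior with a central collecting-system core; per-subject random
    jitter perturbs centers and axes. Every slice contains all five label
    classes, and the classes partition the slice.
    """
    m = meta.matrix_size
    if m < 64:
        raise GeometryError(
            f"matrix_size {m} too small to place all structures (need >= 64)"
        )
    rng = np.random.default_rng(seed)
    shape = (m, m)
    kidneys = []
    for base_cc in (0.32, 0.68):
        cr = (0.42 + rng.uniform(-0.02, 0.02)) * m
        cc = (base_cc + rng.uniform(-0.02, 0.02)) * m
        ar = 0.21 * m * (1 + rng.uniform(-0.05, 0.05))
        ac = 0.13 * m * (1 + rng.uniform(-0.05, 0.05))
        kidneys.append((cr, cc, ar, ac))

    mr0, mr1 = int(0.82 * m), int(0.93 * m)
    mc0, mc1 = int(0.06 * m), int(0.94 * m)

    scales = _slice_scales(meta.n_slices)
    labels = np.zeros((meta.n_slices, m, m), dtype=np.int16)
    kidney_masks = {s: np.zeros((meta.n_slices, m, m), dtype=bool) for s in SIDES}
    for s, scale in enumerate(scales):
        lab = labels[s]
        lab[mr0:mr1, mc0:mc1] = MUSCLE
        for side, (cr, cc, ar, ac) in zip(SIDES, kidneys):
            outer = _ellipse(shape, cr, cc, ar * scale, ac * scale)
            inner = _ellipse(shape, cr, cc, ar * scale * MEDULLA_SCALE, ac * scale * MEDULLA_SCALE)
            core = _ellipse(shape, cr, cc, ar * scale * COLLECTING_SCALE, ac * scale * COLLECTING_SCALE)
            lab[outer] = CORTEX
            lab[inner] = MEDULLA
            lab[core] = COLLECTING_SYSTEM
            kidney_masks[side][s] = outer
        present = set(np.unique(lab))
        if not {BACKGROUND, CORTEX, MEDULLA, COLLECTING_SYSTEM, MUSCLE} <= present:
            raise GeometryError(f"slice {s} is missing a tissue class")
    return ROILabelMap(labels=labels, kidney_masks=kidney_masks)


# ---------------------------------------------------------------------------
# signal simulation
# ---------------------------------------------------------------------------

def sample_b1_field(
    shape: Tuple[int, int], spec: B1FieldSpec, rng: np.random.Generator
) -> np.ndarray:
    """Draw one realized saturation-efficiency field ``s(x, y)``."""
    if spec.amplitude == 0:
        return np.ones(shape)
    ys = np.linspace(-1.0, 1.0, shape[0])[:, None]
    xs = np.linspace(-1.0, 1.0, shape[1])[None, :]
    # Per-degree coefficient scales: the constant (transmit-gain) term
    # dominates the smooth spatial terms ~5:1 in region-mean effect, which
    # is what makes reference-region normalization effective at removing
    # B1 bias; see docs for the calibration argument.
    degree_scale = {0: 1.0, 1: 0.2}
    g = np.zeros(shape)
    for py in range(spec.order + 1):
        for px in range(spec.order + 1 - py):
            scale = degree_scale.get(px + py, 0.1)
            g = g + scale * rng.standard_normal() * (ys ** py) * (xs ** px)
    peak = np.max(np.abs(g))
    if peak == 0:
        return np.ones(shape)
    return 1.0 + spec.amplitude * (g / peak)


def _rician(x: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    real = x + rng.normal(0.0, sigma, x.shape)
    imag = rng.normal(0.0, sigma, x.shape)
    return np.hypot(real, imag)


@dataclass(frozen=True)
class SimulatedAcquisition:
    """One synthetic acquisition: images, anatomical reference, realized B1."""

    images: MTImageSet
    anatomical: np.ndarray
    b1_field: np.ndarray


def simulate_acquisition(
    labels: ROILabelMap,
    truth: TissueTruth,
    meta: AcquisitionMeta,
    b1: B1FieldSpec = B1FieldSpec(),
    noise: NoiseSpec = NoiseSpec(snr=math.inf),
    seed=0,
) -> SimulatedAcquisition:
    """Simulate paired M0/MT stacks plus the anatomical reference.

    In the noiseless, uniform-B1 limit the computed MTR map equals the
    class-wise truth to machine precision.
    """
    lab = labels.labels
    rng = np.random.default_rng(seed)
    s2d = sample_b1_field(lab.shape[1:], b1, rng)

    mtr_true = np.zeros(lab.shape)
    mtr_true[lab == MUSCLE] = truth.muscle_mtr
    mtr_true[lab == COLLECTING_SYSTEM] = truth.collecting_mtr
    for side, mask in labels.kidney_masks.items():
        side_truth = truth.kidney_mtr[side]
        mtr_true[(lab == CORTEX) & mask] = side_truth["cortex"]
        mtr_true[(lab == MEDULLA) & mask] = side_truth["medulla"]

    m0 = (lab != BACKGROUND).astype(float)
    saturation = s2d[None, :, :] * mtr_true
    if saturation.max() >= 1.0:
        raise ValidationError("B1-scaled true MTR reaches 1; reduce amplitude or MTR")
    mt = m0 * (1.0 - saturation)

    lut = np.array(
        [truth.anatomical_intensity[LABELS_BY_ID[i]] for i in range(5)]
    )
    anatomical = lut[lab]

    if math.isfinite(noise.snr):
        sigma = 1.0 / noise.snr
        m0 = _rician(m0, sigma, rng)
        mt = _rician(mt, sigma, rng)
        anatomical = _rician(anatomical, sigma, rng)

    return SimulatedAcquisition(
        images=MTImageSet(m0=m0, mt=mt, meta=meta),
        anatomical=anatomical,
        b1_field=s2d,
    )


LABELS_BY_ID = {
    BACKGROUND: "background",
    CORTEX: "cortex",
    MEDULLA: "medulla",
    COLLECTING_SYSTEM: "collecting_system",
    MUSCLE: "muscle",
}


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _default_b1_amplitude() -> Dict[float, float]:
    return {1.5: 0.05, 3.0: 0.05}


def _default_snr() -> Dict[float, float]:
    return {1.5: 20.0, 3.0: 40.0}


def _default_decrement() -> Dict[str, float]:
    return {"normal": 0.02, "stenotic": 0.0, "contralateral": 0.0}


@dataclass
class CohortSpec:
    """Study-design parameters of a synthetic cohort.

    Defaults reproduce the emulated study: 9 RAS + 6 sham subjects, both
    field strengths, both offsets, two timepoints, 128x128 matrix with five
    slices, SNR 40 at 3 T vs 20 at 1.5 T, B1 amplitude 5 %, and normalized
    tissue truths (mean, SD) from :data:`TABLE1_NORMALIZED_MTR`.
    """

    n_ras: int = 9
    n_sham: int = 6
    matrix_size: int = 128
    n_slices: int = 5
    field_strengths: Sequence[float] = (1.5, 3.0)
    offset_frequencies: Sequence[int] = (600, 1000)
    timepoints: Sequence[int] = (1, 2)
    muscle_mtr: float = 0.40
    collecting_mtr: float = 0.10
    truth_table: Dict[Tuple[float, int], Dict[str, Dict[str, Tuple[float, float]]]] = dc_field(
        default_factory=lambda: copy.deepcopy(TABLE1_NORMALIZED_MTR)
    )
    jitter_scale: float = 1.0
    tp2_decrement: Dict[str, float] = dc_field(default_factory=_default_decrement)
    b1_amplitude: Dict[float, float] = dc_field(default_factory=_default_b1_amplitude)
    b1_order: int = 2
    snr: Dict[float, float] = dc_field(default_factory=_default_snr)
    anatomical_intensity: Dict[str, float] = dc_field(
        default_factory=lambda: dict(DEFAULT_ANATOMICAL_INTENSITY)
    )

    def __post_init__(self) -> None:
        if self.n_ras < 0 or self.n_sham < 0:
            raise ValidationError("subject counts must be >= 0")
        if self.jitter_scale < 0:
            raise ValidationError("jitter_scale must be >= 0")
        for stratum in self.truth_table.values():
            for region in stratum.values():
                for mean, sd in region.values():
                    if sd < 0:
                        raise ValidationError("truth SDs must be >= 0")
                    if not 0 < mean:
                        raise ValidationError("truth means must be > 0")

    def subjects(self) -> list:
        """(subject_id, group, {side: role}) tuples, RAS first."""
        out = []
        for i in range(self.n_ras):
            out.append(
                (f"ras{i + 1:02d}", "RAS", {"left": "stenotic", "right": "contralateral"})
            )
        for i in range(self.n_sham):
            out.append((f"sham{i + 1:02d}", "sham", {"left": "normal", "right": "normal"}))
        return out


def draw_cohort_truths(spec: CohortSpec, seed: int) -> pd.DataFrame:
    """Draw per-subject normalized tissue truths for every stratum.

    One Gaussian draw per (subject, kidney side, field, offset, region),
    shared across timepoints; timepoint 2 applies the role's configured
    decrement. Each (subject, side, field, offset) gets its own seed stream,
    so restricting the generated strata never reshuffles the others.
    """
    rows = []
    for si, (sid, group, roles) in enumerate(spec.subjects()):
        for side_i, side in enumerate(SIDES):
            role = roles[side]
            for f in spec.field_strengths:
                for off in spec.offset_frequencies:
                    ss = np.random.SeedSequence(
                        seed, spawn_key=(2, si, side_i, int(f * 10), int(off))
                    )
                    rng = np.random.default_rng(ss)
                    for region in REGIONS:
                        mean, sd = spec.truth_table[(f, off)][region][role]
                        v1 = float(
                            np.clip(
                                mean + spec.jitter_scale * sd * rng.standard_normal(),
                                *_NORM_TRUTH_CLIP,
                            )
                        )
                        for tp in spec.timepoints:
                            v = v1
                            if tp == 2:
                                v = float(
                                    np.clip(
                                        v1 - spec.tp2_decrement.get(role, 0.0),
                                        *_NORM_TRUTH_CLIP,
                                    )
                                )
                            rows.append(
                                dict(
                                    subject=sid,
                                    group=group,
                                    side=side,
                                    role=role,
                                    field_T=f,
                                    offset_hz=off,
                                    timepoint=tp,
                                    region=region,
                                    norm_truth=v,
                                )
                            )
    return pd.DataFrame(rows)


@dataclass
class AcquisitionRecord:
    """One acquisition of one subject, with its ground truth when simulated.

    Records read from disk may lack the truth fields (``None``) and may
    carry a user-drawn muscle ROI instead.
    """

    meta: AcquisitionMeta
    images: MTImageSet
    anatomical: Optional[np.ndarray] = None
    b1_field: Optional[np.ndarray] = None
    truth: Optional[TissueTruth] = None
    norm_truth: Optional[Dict[Tuple[str, str], float]] = None  # (side, region) -> normalized truth
    user_muscle: Optional[np.ndarray] = None


@dataclass
class SubjectRecord:
    subject_id: str
    group: str
    roles: Dict[str, str]
    geometry: ROILabelMap
    acquisitions: Dict[Tuple[float, int, int], AcquisitionRecord]


@dataclass
class PhantomDataset:
    """A fully synthetic cohort with per-pixel and per-tissue ground truth."""

    spec: CohortSpec
    master_seed: int
    subjects: list


def generate_cohort(spec: CohortSpec = None, seed: int = 0) -> PhantomDataset:
    """Generate the full synthetic cohort for every configured stratum.

    Per-subject geometry and per-acquisition simulation seeds are derived
    from the master seed via :class:`numpy.random.SeedSequence` spawn keys
    over (subject, field, offset, timepoint), so identical spec + seed give
    bit-identical datasets and edits to one stratum leave others untouched.
    """
    if spec is None:
        spec = CohortSpec()
    truths = draw_cohort_truths(spec, seed)
    idx = truths.set_index(
        ["subject", "side", "field_T", "offset_hz", "timepoint", "region"]
    )["norm_truth"]

    subjects = []
    for si, (sid, group, roles) in enumerate(spec.subjects()):
        geo_meta = AcquisitionMeta(
            field_strength=spec.field_strengths[0] if 3.0 not in spec.field_strengths else 3.0,
            offset_frequency=int(spec.offset_frequencies[0]),
            matrix_size=spec.matrix_size,
            n_slices=spec.n_slices,
        )
        geometry = build_geometry(geo_meta, np.random.SeedSequence(seed, spawn_key=(1, si)))
        acquisitions = {}
        for f in spec.field_strengths:
            for off in spec.offset_frequencies:
                for tp in spec.timepoints:
                    meta = AcquisitionMeta(
                        field_strength=f,
                        offset_frequency=int(off),
                        timepoint=int(tp),
                        matrix_size=spec.matrix_size,
                        n_slices=spec.n_slices,
                    )
                    norm = {
                        (side, region): float(idx.loc[(sid, side, f, off, tp, region)])
                        for side in SIDES
                        for region in REGIONS
                    }
                    truth = TissueTruth(
                        kidney_mtr={
                            side: {
                                region: norm[(side, region)] * spec.muscle_mtr
                                for region in REGIONS
                            }
                            for side in SIDES
                        },
                        muscle_mtr=spec.muscle_mtr,
                        collecting_mtr=spec.collecting_mtr,
                        anatomical_intensity=dict(spec.anatomical_intensity),
                    )
                    sim = simulate_acquisition(
                        geometry,
                        truth,
                        meta,
                        b1=B1FieldSpec(amplitude=spec.b1_amplitude[f], order=spec.b1_order),
                        noise=NoiseSpec(snr=spec.snr[f]),
                        seed=np.random.SeedSequence(
                            seed, spawn_key=(3, si, int(f * 10), int(off), int(tp))
                        ),
                    )
                    acquisitions[(f, int(off), int(tp))] = AcquisitionRecord(
                        meta=meta,
                        images=sim.images,
                        anatomical=sim.anatomical,
                        b1_field=sim.b1_field,
                        truth=truth,
                        norm_truth=norm,
                    )
        subjects.append(
            SubjectRecord(
                subject_id=sid,
                group=group,
                roles=roles,
                geometry=geometry,
                acquisitions=acquisitions,
            )
        )
    return PhantomDataset(spec=spec, master_seed=seed, subjects=subjects)
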