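"""Phantom generator: geometry, forward model, cohort structure."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import renalmtr as rm
from renalmtr.segmentation import (
    BACKGROUND,
    COLLECTING_SYSTEM,
    CORTEX,
    MEDULLA,
    MUSCLE,
)

ALL_CLASSES = {BACKGROUND, CORTEX, MEDULLA, COLLECTING_SYSTEM, MUSCLE}


class TestGeometry:
    def test_every_slice_partitions_into_all_five_classes(self, geometry128):
        for s in range(geometry128.labels.shape[0]):
            assert set(np.unique(geometry128.labels[s])) == ALL_CLASSES

    def test_kidney_masks_are_disjoint_and_cover_kidney_labels(self, geometry128):
        left = geometry128.kidney_masks["left"]
        right = geometry128.kidney_masks["right"]
        assert not (left & right).any()
        kidney_labels = np.isin(geometry128.labels, [CORTEX, MEDULLA, COLLECTING_SYSTEM])
        assert np.array_equal(kidney_labels, left | right)

    def test_cortex_forms_rim_around_medulla(self, geometry128):
        # every medulla pixel of a kidney is enclosed by that kidney's cortex:
        # walking outward along rows/cols from the medulla must hit cortex
        from scipy import ndimage

        lab = geometry128.labels[2]
        left = geometry128.kidney_masks["left"][2]
        medulla = (lab == MEDULLA) & left
        cortex = (lab == CORTEX) & left
        grown = ndimage.binary_dilation(medulla, iterations=2)
        ring = grown & ~ndimage.binary_dilation(medulla, iterations=0) & ~medulla
        # the 2-px ring around the medulla lies within kidney (cortex rim >= 2 px
        # means no background directly abuts the medulla)
        assert not (ring & (lab == BACKGROUND)).any()
        assert cortex.sum() > 0

    def test_same_seed_reproduces_identical_geometry(self, meta128):
        a = rm.build_geometry(meta128, seed=7)
        b = rm.build_geometry(meta128, seed=7)
        assert np.array_equal(a.labels, b.labels)
        assert all(
            np.array_equal(a.kidney_masks[s], b.kidney_masks[s]) for s in a.kidney_masks
        )

    def test_too_small_matrix_raises_geometry_error(self):
        meta = rm.AcquisitionMeta(3.0, 600, matrix_size=32)
        with pytest.raises(rm.GeometryError):
            rm.build_geometry(meta, seed=1)

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), matrix=st.sampled_from([64, 96, 128]))
    def test_partition_property_across_seeds_and_sizes(self, seed, matrix):
        meta = rm.AcquisitionMeta(3.0, 600, matrix_size=matrix, n_slices=2)
        geo = rm.build_geometry(meta, seed)
        for s in range(2):
            assert set(np.unique(geo.labels[s])) == ALL_CLASSES


class TestSimulateAcquisition:
    def test_noiseless_uniform_b1_recovers_truth_exactly(
        self, geometry128, truth_3t600, noiseless_sim
    ):
        m0, mt = noiseless_sim.images.m0, noiseless_sim.images.mt
        with np.errstate(invalid="ignore"):
            mtr = (m0 - mt) / m0
        cortex_left = (geometry128.labels == CORTEX) & geometry128.kidney_masks["left"]
        assert np.allclose(mtr[cortex_left], 0.75 * 0.40, atol=1e-15)
        muscle = geometry128.labels == MUSCLE
        assert np.allclose(mtr[muscle], 0.40, atol=1e-15)

    def test_fixed_seed_gives_bit_identical_images(self, geometry128, truth_3t600, meta128):
        kwargs = dict(
            b1=rm.B1FieldSpec(0.05), noise=rm.NoiseSpec(snr=40), seed=42
        )
        a = rm.simulate_acquisition(geometry128, truth_3t600, meta128, **kwargs)
        b = rm.simulate_acquisition(geometry128, truth_3t600, meta128, **kwargs)
        assert np.array_equal(a.images.m0, b.images.m0)
        assert np.array_equal(a.images.mt, b.images.mt)
        assert np.array_equal(a.anatomical, b.anatomical)

    def test_b1_field_scales_observed_mtr_pixelwise(self, geometry128, truth_3t600, meta128):
        """Noiseless MTR equals s(x,y) * true MTR; the realized field bounds
        the normalized-ratio deviation."""
        sim = rm.simulate_acquisition(
            geometry128,
            truth_3t600,
            meta128,
            b1=rm.B1FieldSpec(amplitude=0.10),
            noise=rm.NoiseSpec(snr=math.inf),
            seed=5,
        )
        s2d = sim.b1_field
        assert np.all(np.abs(s2d - 1) <= 0.10 + 1e-12)
        m0, mt = sim.images.m0, sim.images.mt
        lab = geometry128.labels
        cortex = (lab == CORTEX) & geometry128.kidney_masks["left"]
        muscle = lab == MUSCLE
        with np.errstate(invalid="ignore"):
            mtr = (m0 - mt) / m0
        expected = np.broadcast_to(s2d, lab.shape) * 0.75 * 0.40
        assert np.allclose(mtr[cortex], expected[cortex], atol=1e-12)
        # regional ratio deviates from the truth ratio by the field's
        # kidney-vs-muscle mean contrast, within the amplitude bound
        ratio = mtr[cortex].mean() / mtr[muscle].mean()
        s_ratio = (
            np.broadcast_to(s2d, lab.shape)[cortex].mean()
            / np.broadcast_to(s2d, lab.shape)[muscle].mean()
        )
        assert ratio == pytest.approx(0.75 * s_ratio, abs=1e-12)
        assert abs(ratio - 0.75) < 0.10 * 0.75

    def test_mtr_truth_out_of_range_rejected(self):
        with pytest.raises(rm.ValidationError):
            rm.TissueTruth(kidney_mtr={"left": {"cortex": 1.2, "medulla": 0.3},
                                       "right": {"cortex": 0.3, "medulla": 0.3}})

    def test_anatomical_contrast_constraint_enforced(self):
        with pytest.raises(rm.ValidationError):
            rm.TissueTruth(
                kidney_mtr={"left": {"cortex": 0.3, "medulla": 0.3},
                            "right": {"cortex": 0.3, "medulla": 0.3}},
                anatomical_intensity={
                    "background": 0.0,
                    "cortex": 0.5,
                    "medulla": 0.9,  # brighter than cortex: invalid
                    "collecting_system": 0.1,
                    "muscle": 0.8,
                },
            )


class TestCohort:
    def test_default_structure_ras_and_sham_roles(self, tiny_spec):
        ds = rm.generate_cohort(tiny_spec, seed=7)
        assert len(ds.subjects) == 3
        ras = [s for s in ds.subjects if s.group == "RAS"]
        sham = [s for s in ds.subjects if s.group == "sham"]
        assert len(ras) == 2 and len(sham) == 1
        for s in ras:
            assert sorted(s.roles.values()) == ["contralateral", "stenotic"]
        for s in sham:
            assert list(s.roles.values()) == ["normal", "normal"]
        assert all(len(s.acquisitions) == 1 for s in ds.subjects)

    def test_zero_jitter_gives_identical_same_role_truths(self, tiny_spec):
        tiny_spec.jitter_scale = 0.0
        truths = rm.draw_cohort_truths(tiny_spec, seed=3)
        stk = truths[(truths.role == "stenotic") & (truths.region == "cortex")]
        assert stk.norm_truth.nunique() == 1
        assert stk.norm_truth.iloc[0] == pytest.approx(0.75)

    def test_negative_counts_rejected(self):
        with pytest.raises(rm.ValidationError):
            rm.CohortSpec(n_ras=-1)

    def test_between_subject_jitter_matches_configured_sd(self):
        """Monte-Carlo: pooled SD of stenotic-cortex truths at 3T/600 is
        within 50% of the configured 0.08 across many seeded cohorts."""
        spec = rm.CohortSpec(
            n_sham=0, field_strengths=(3.0,), offset_frequencies=(600,), timepoints=(1,)
        )
        draws = []
        for seed in range(150):
            t = rm.draw_cohort_truths(spec, seed)
            sel = t[(t.role == "stenotic") & (t.region == "cortex")]
            assert len(sel) == 9
            draws.append(sel.norm_truth.to_numpy())
        sd = np.concatenate(draws).std(ddof=1)
        assert 0.5 * 0.08 < sd < 1.5 * 0.08

    def test_timepoint2_decrement_applies_to_normal_kidneys_only(self):
        spec = rm.CohortSpec(
            n_ras=1, n_sham=1, field_strengths=(3.0,), offset_frequencies=(600,)
        )
        t = rm.draw_cohort_truths(spec, seed=1)
        piv = t.pivot_table(
            index=["subject", "side", "role", "region"],
            columns="timepoint",
            values="norm_truth",
        )
        diff = piv[1] - piv[2]
        roles = piv.index.get_level_values("role")
        assert np.allclose(diff[roles == "normal"], 0.02)
        assert np.allclose(diff[roles != "normal"], 0.0)

    def test_same_seed_gives_identical_cohort(self, tiny_spec):
        a = rm.generate_cohort(tiny_spec, seed=11)
        b = rm.generate_cohort(tiny_spec, seed=11)
        ka = a.subjects[0].acquisitions
        kb = b.subjects[0].acquisitions
        for key in ka:
            assert np.array_equal(ka[key].images.m0, kb[key].images.m0)
            assert np.array_equal(ka[key].images.mt, kb[key].images.mt)
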