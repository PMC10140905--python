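# renalmtr

Magnetization-transfer-ratio (MTR) analysis of renal fibrosis for MT-MRI
studies, with a fully ground-truthed digital kidney phantom.

Renal fibrosis — accumulation of collagen and other extracellular matrix in
chronic kidney disease — raises the macromolecular proton pool of the
tissue. Magnetization transfer imaging sensitizes the MR signal to that
pool: an off-resonance saturation pulse saturates macromolecule-bound
protons, and exchange with free water attenuates the visible signal. The
magnetization transfer ratio

```
MTR = (M0 − MT) / M0
```

(`M0`: image without MT preparation, `MT`: MT-weighted image) quantifies
that attenuation pixel-wise; fibrotic tissue shows a higher MTR. Because
transmit-field (B1) inhomogeneity scales the saturation efficiency and
biases MTR, kidney regional values are normalized by the MTR of a
dorsal-muscle reference ROI measured on the same slice.

The package is aimed at quantitative-MRI methods work: it implements the
complete analysis chain for a two-arm animal study (subjects with
unilateral renal artery stenosis carrying one stenotic and one
contralateral kidney, versus sham controls with normal kidneys, imaged at
1.5 T and 3 T, 600 and 1000 Hz MT offsets, at two timepoints), and a
synthetic-cohort generator with known tissue truths for validating every
stage and for power studies.

## What it provides

- `phantom` — synthetic MT-weighted renal cohorts: elliptical-annulus
  kidney geometry (cortex rim, medullary interior, collecting-system core,
  dorsal muscle band), forward model `MT = M0·(1 − s(x,y)·MTR_true)` with a
  smooth multiplicative B1 saturation-efficiency field `s`, Rician
  magnitude noise, per-subject between-subject truth jitter, full per-pixel
  ground truth.
- `mtr` — pixel-wise MTR maps with background masking and a validity mask.
- `segmentation` — semi-automatic cortex/medulla segmentation on the
  anatomical reference (collecting-system exclusion → threshold →
  morphological opening → border extraction), automatic or user-supplied
  dorsal-muscle ROI, Dice validation metric.
- `regional` — per-slice ROI means, muscle normalization, per-subject
  summaries (sham kidneys averaged so the unit of analysis is the animal).
- `stats` — Wilcoxon rank-sum group contrasts (exact by complete
  enumeration for small tie-free samples), paired-t field-strength and
  test-retest comparisons, the full comparison grid, optional Holm
  adjustment.
- `pipeline` / `cli` — end-to-end orchestration with deterministic seeding,
  CSV/NIfTI/JSON outputs, QC figures, and a `renalmtr` command
  (`simulate`, `analyze mtr|segment|summarize`, `stats`, `run`).

## Worked example

Simulate the default cohort restricted to 3 T / 600 Hz at the first
timepoint, run the pipeline, and test the stenotic-vs-contralateral cortex
contrast:

```python
import renalmtr as rm

spec = rm.CohortSpec(field_strengths=(3.0,), offset_frequencies=(600,),
                     timepoints=(1,))
dataset = rm.generate_cohort(spec, seed=1)
measurements = rm.measure_dataset(dataset)      # estimated segmentations
summary = rm.summarize_subjects(measurements)

print(summary.groupby(["role", "region"])["norm_mtr"].mean().round(3))

cortex = summary[summary.region == "cortex"]
result = rm.rank_sum_test(
    cortex[cortex.role == "stenotic"].norm_mtr,
    cortex[cortex.role == "contralateral"].norm_mtr,
)
print(f"STK vs CLK cortex: W={result.statistic:.0f}, p={result.p_value:.4f}")
```

Output:

```
role           region
contralateral  cortex     0.679
               medulla    0.537
normal         cortex     0.699
               medulla    0.644
stenotic       cortex     0.745
               medulla    0.750
Name: norm_mtr, dtype: float64
STK vs CLK cortex: W=105, p=0.0934
```

The group means are muscle-normalized MTRs: stenotic cortex ≈ 0.745
against a configured truth of 0.75, contralateral ≈ 0.679 against 0.64 —
each group mean scatters around its truth with SE ≈ SD/√9 ≈ 0.027 from
between-subject variation, so individual seeds can sit a couple of
hundredths off. The rank-sum p-value for this particular seed (0.094)
illustrates that a single cohort of 9 vs 9 is near the edge of the design's
power; across many seeds the contrast is significant in roughly three
quarters of cohorts (see the acceptance suite).

The same run from the shell:

```
renalmtr run --seed 1 --out out/        # writes measurements.csv,
                                        # summary.csv, stats.csv,
                                        # report.txt, manifest.json
```

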