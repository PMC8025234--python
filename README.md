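# synaptoquant

A quantification pipeline for presynaptic cell biology. It covers the
measurement chain used when studying how presynaptic precursor vesicles are
made and delivered in *Drosophila* motoneurons: fluorescent puncta counting
at neuromuscular junctions and in ventral-nerve-cord somata, colocalization
and spatial-segregation statistics with explicit chance controls,
kymograph-based axonal transport analysis, electron-microscopy vesicle
morphometry, evoked-current parameter extraction, and the normality-gated
statistics that decide which test a comparison gets.

Raw microscopy/electrophysiology recordings for this kind of study are
rarely deposited, so the package ships a first-class synthetic-data module:
every input class the pipeline consumes can be generated with known ground
truth, which makes every stage testable end to end.

## What it computes

**Puncta quantification** (`synaptoquant.quantify`). Maximum projection →
background subtraction → manual (or Otsu) threshold → Gaussian blur (σ =
0.5 px) for segmentation only → prominence-filtered local maxima +
marker-seeded watershed → per-particle area, centroid and integrated
density on the original intensities. Field summaries: particle density
(n / reference area), summed integrated density per area, percent-of-control
normalization (control mean = 100 %). Ring-shaped puncta get an equivalent
diameter d = 2√(A/π); bouton cytoplasmic intensity is measured after
excluding bright subregions found on a σ = 2.0 blurred copy above an
intensity threshold.

**Colocalization** (`synaptoquant.coloc`). Pearson's r over ROI pixels
above per-channel thresholds, with the chance control recomputed after
mirroring the second channel left–right inside the ROI bounding box; binary
mask area-overlap percentages.

**Spatial segregation** (`synaptoquant.spatial`). Line-profile peak-to-peak
distances binned at 0.06 µm up to a 1.2 µm cutoff, with a wrap-around
80-pixel shift of the second channel as the chance distribution; and
center-of-mass distances d = √((x₁−x₂)² + (y₁−y₂)²) between the
intensity-weighted centroids of two channels' structures.

**Axonal transport** (`synaptoquant.transport`). Translation registration
(phase correlation), kymograph construction along a proximal-first path
(one row per frame), streak detection with unidirectionality and
"≥ 4 µm and ≥ 30 s" gates, speed = path length / duration, direction from
slope sign, and cotransport classification (second channel above threshold
in ≥ 3 distinct frames along the track).

**EM morphometry** (`synaptoquant.morphometry`). Moment-ellipse long/short
diameters and elongation (long/short ≥ 1) per labeled vesicle profile,
stereological volume fraction by the Delesse principle, 3-D volume and
marching-cubes surface area of reconstructed bodies, and T-bar annotation
geometry (polyline lengths, shoelace polygon area).

**Evoked currents** (`synaptoquant.ephys`). Amplitude (signed, peak −
baseline), 10–90 % rise time, mono-exponential decay τ, charge ∫(I −
baseline)dt, and the paired-pulse ratio A₂/A₁ with the first response's
fitted decay extrapolated under the second peak.

**Statistics** (`synaptoquant.stats`). Per group D'Agostino–Pearson
normality at α = 0.05 (n < 8 assumed normal); two groups → unpaired t or
Mann–Whitney U; more groups → one-way ANOVA + Tukey or Kruskal–Wallis +
Dunn; star annotation (*, **, *** at p < 0.05/0.01/0.001) and
percent-of-control normalization.

## Worked example

Generate a noisy field of 200 diffraction-blurred puncta (peak SNR ≈ 5,
0.1 µm pixels) and quantify it:

```python
from synaptoquant import synthdata as sd
from synaptoquant.quantify import DetectionConfig, segment_particles, summarize_field

spec = sd.PunctaFieldSpec(n_puncta=200, min_separation=8.0, seed=1)
img, truth = sd.generate_puncta_field(spec)
cfg = DetectionConfig(threshold=60.0, min_particle_area=9, maxima_prominence=40.0)
table = segment_particles(img, cfg=cfg)
summary = summarize_field(table, reference_area_um2=img.data.size * spec.pixel_size**2)
print(f"true puncta:      {len(truth.records)}")
print(f"detected puncta:  {table.n_particles}")
print(summary.round(4).to_string())
```

prints

```
true puncta:      200
detected puncta:  204
n_particles                       204.0000
reference_area_um2                655.3600
density_per_um2                     0.3113
sum_intensity_per_area_au_um2    3708.3152
mean_particle_area_um2              1.3708
```

204 of 200 true puncta detected (2 % count error at SNR 5): the density and
sum-intensity-per-area values are the quantities a genotype comparison
would feed into `synaptoquant.stats.compare_table`, normalized to the
control group's mean.

The same operations are available from the shell:

```sh
synaptoquant simulate --kind puncta --seed 1 --out sim/
synaptoquant quantify-puncta --image sim/puncta.tif --threshold 60 --out out/
synaptoquant stats --table metrics.csv --group-col genotype --value-col density --control wt --out cmp.csv
```

plus `coloc`, `distances`, `kymo`, `morpho`, `ephys`, and a config-driven
`run`.

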