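# sozdensity

Tools for studying how intracranial electrode **density** affects
delineation of the **seizure onset zone (SOZ)** — the brain tissue targeted
in epilepsy surgery. Higher-density (HD) subdural grids (4 mm contact
spacing) and depth probes (5 mm) can be digitally decimated to the
lower-density (LD) spacings of conventional clinical recordings (8–10 mm),
and the two conditions compared on blinded seizure-intensity heatmaps,
scorer-annotation agreement, and simulated SOZ volume estimation.

The package is aimed at clinical-neurophysiology researchers who want to
reproduce, extend, or stress-test this comparison. Because raw patient
ICEEG is not redistributable, every pipeline input can be generated
synthetically with known ground truth.

## What it computes

**Seizure-intensity heatmaps.** Each channel's intensity is the
line-length transform — over a trailing window of the signal $x$,

$$LL(t) = \sum_{i \in (t - w,\, t]} |x_i - x_{i-1}|,$$

z-scored per channel against a pre-ictal baseline. Intensity is projected
onto anatomy (surface-mesh vertices or omni-planar slice pixels through
each depth probe) with a distance-based Gaussian drop-off, taking the
**maximum** over nearby electrodes:

$$\mathrm{heat}(p) = \max_{e\,:\,d(e,p)\le c}\; z_e\, e^{-d(e,p)^2 / 2\sigma^2}.$$

The max (rather than a sum) keeps the display from brightening merely
because more electrodes are present, which would unblind the density
condition; it also makes decimation provably non-increasing: LD heat never
exceeds HD heat anywhere.

**Agreement statistics.** Scorer SOZ annotations are binary pixel masks;
agreement between two scorers is unweighted Cohen's kappa over all pixels
in the raster, $\kappa = (p_o - p_e)/(1 - p_e)$, computed pairwise across
scorers (inter-rater) and across conditions within a scorer (intra-rater).

**Crossover inference.** Outcomes from the balanced single-blinded
crossover design (every scorer, every seizure, both conditions) are
analysed with linear mixed models carrying crossed random intercepts for
scorer and seizure: log annotated area and Likert confidence on density,
multifocality, and clinical-SOZ overlap; pairwise kappa on density; plus a
carryover check (first-shown condition as an extra predictor). A density
coefficient $b$ on log area converts to a percent difference as
$100(e^{b}-1)$. Design-effect and noncentral-t power utilities cover the
effective-sample-size reasoning.

**Spatial-sampling simulation.** A spherical true SOZ is placed in nested
electrode lattices (1 / 5 / 10 mm spacing); the estimated SOZ is the convex
hull of contacts inside the sphere. Lattice nesting makes the estimate
provably monotone in density and always an underestimate, quantifying how
coarser sampling shrinks the apparent SOZ.

## Worked example

```python
import numpy as np
from sozdensity import agreement, density, geometry, heatmap, inference, synthetic

# a synthetic focal seizure on an 8x8 HD grid
grid = geometry.build_grid_array(8, 8, 4.0, array_id="G")
cfg = synthetic.SeizureSimConfig(seed=3, duration_s=12.0, onset_s=8.0,
                                 focus=(12.5, 13.0, 0.0))
rec = synthetic.generate_seizure_recording([grid], cfg)

# HD -> LD decimation and heat projection
ld, cond = density.subsample_grid(grid)
ll = heatmap.line_length(rec)
b0, b1 = rec.baseline_window
z = heatmap.zscore_to_baseline(ll, (b0 / rec.fs_hz, b1 / rec.fs_hz))
fr = z.frames_in(9.0, 12.0)[-1]
targets = grid.contacts + np.array([0.0, 0.0, 2.0])
hd_heat = heatmap.project_max_gaussian(z.values[:, fr], grid.contacts, targets)
idx = np.array(cond.retained_contact_indices)
ld_heat = heatmap.project_max_gaussian(z.values[idx, fr], ld.contacts, targets)

# simulated scorers and the crossover mixed model
truth = synthetic.generate_true_soz_mask((120, 120), radius_px=25.0)
masks = synthetic.simulate_scorer_annotations(
    truth, "HD", synthetic.ScorerSimConfig(seed=3))
kappas = [r.kappa for r in agreement.pairwise_kappa(masks)]
res = inference.fit_area_model(synthetic.generate_score_table(seed=3))
```

Output of the full script (see the calls above):

```
recording: 64 channels x 36624 samples @ 3052 Hz
decimation: 4 mm grid -> 8 mm, 64 -> 16 contacts
peak heat (z-units): HD 35.2 vs LD 19.8
pairwise kappa over 15 scorer pairs: mean 0.86
area model density coefficient: 0.247 (95% CI 0.135 to 0.359, p = 0.0000)
implied HD area increase: 28.0%
minimum detectable effect at n=20/arm: d = 0.91
```

The peak heat line shows the decimation effect directly: removing every
other row and column can only lower the displayed intensity (here the LD
peak is the HD peak seen from farther away). The score table was generated
with a true density effect of 0.227 on log area; the fitted coefficient
0.247 recovers it within its confidence interval, and the percent
transform turns it into the "HD annotations ~25% larger" reading.

A command-line interface mirrors the main steps (`sozdensity
synth-recording`, `density-subsample`, `kappa`, `power`, `densitysim`,
…); run `sozdensity --help`.

## Layout

- `sozdensity.geometry` — electrode arrays (grid/strip/depth), brain
  meshes (PLY), omni-planar slice bases
- `sozdensity.synthetic` — seizure recordings, true SOZ masks, simulated
  scorers, crossover schedules, score tables with known parameters
- `sozdensity.preprocess` — anti-alias resampling, mains notch filters,
  bad-channel exclusion; HDF5 recording container
- `sozdensity.density` — HD→LD decimation of arrays and recordings
- `sozdensity.heatmap` — line length, baseline z-scoring, max-Gaussian
  projection, blinded rendering
- `sozdensity.agreement` — polygon rasterisation, Cohen's kappa,
  clinical-overlap flags
- `sozdensity.inference` — mixed models, carryover, power utilities
- `sozdensity.density_sim` — lattice SOZ-volume sweep

See `docs/methods.md` for modelling assumptions and parameter choices.
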