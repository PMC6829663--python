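# tirfgran

Quantitative analysis of secretory-granule behaviour at the plasma
membrane in TIRF (total internal reflection fluorescence) microscopy
movies: spot detection and granule density, dwell-time docking
classification, abrupt-loss fusion (exocytosis) event detection, a
structure-centered enrichment statistic for two-channel colocalization,
and F/F0 quantification of whole-footprint reporter traces.  A
ground-truth movie simulator makes every stage testable against known
kinetics, and a thin CLI ties the stages into reproducible runs.

The package is aimed at cell biologists quantifying insulin-granule (or
other dense-core vesicle) docking and release from time-lapse TIRF
recordings, where only the ~100–200 nm of cytosol nearest the coverslip
is illuminated and granules appear as diffraction-limited spots.

## Core methods

**Spot detection.** Granules are local maxima of the Gaussian-smoothed
frame whose prominence (height above the highest saddle; the h-maxima
criterion, equivalent to an ImageJ "find maxima" noise tolerance)
exceeds a threshold — by default five robust (MAD-based) standard
deviations of the smoothed background.  Granule density is spot count
over footprint area (pixel size 100 nm by default).

**Docking classification.** Detections are linked into tracks (greedy
nearest-neighbour, gap closing), then classified by dwell time: a
granule that appears and stays laterally confined (max excursion from
its median position ≤ 1.5 px) for ≥ 2 s is an *approach*; with confined
residence ≥ 25 s it is *docked*, otherwise a *visitor*; unconfined
tracks are *transit*.  Stable docking compares approaches (0 s) with
those still present 40 s later.

**Fusion detection.** Exocytosis shows as loss of the granule marker
within one or two frames.  An event is called where the
background-corrected spot intensity collapses from a stable pre-level
to below half of it within ≤ 2 frames, stays down over the following
five frames, and no spot re-appears within 2 px.

**Enrichment statistic.** For ≥ 15 structures per cell, 30×30-px crops
centered on the marker are averaged; a diagonal line profile (42
samples for a 30-px crop) is drawn; the granule width N_gr is the
marker profile's FWHM above its minimum *min*; and the probe enrichment
is

    E = (AUC_gr − N_gr·min) / (AUC_All − N_All·min)

which approaches N_gr/N_All for an unenriched probe and 1 for a fully
granule-bound one.

**Traces.** Footprint traces are background-corrected and normalized to
the pre-stimulus mean (F/F0); the module reports the maximal response
and the post-stimulus reuptake time constant from a single-exponential
fit y(t) = A·exp(−t/τ) + C.

## Worked example

```python
import tirfgran as tg
from tirfgran.pipelines import run_docking_measurement

# enrichment of a probe that is 60% granule-bound, 20 structures
ch1, ch2, _ = tg.simulate_crop_pair(20, granule_amplitude=200.0,
                                    bound_fraction=0.6, wide_bg_sigma=8.0, seed=11)
res = tg.enrichment_from_crops(ch1, ch2)
print(f"N_gr = {res.n_gr:.2f} samples, N_All = {res.n_all}")
print(f"E = {res.E:.3f}   E_null = N_gr/N_All = {res.E_null:.3f}")

# stable docking on a simulated movie with a 50% long-lived share
run = run_docking_measurement(seed=77, n_approaches=80, p_dock=0.5,
                              image_shape=(192, 192), n_frames=220,
                              arrival_window=(5, 170))
print(f"approaches = {run.n_approach}, stable at 40 s = {run.n_stable}, "
      f"stable docking = {run.stable_pct:.1f}%")
```

prints

```
N_gr = 4.44 samples, N_All = 42
E = 0.698   E_null = N_gr/N_All = 0.106
approaches = 79, stable at 40 s = 31, stable docking = 39.2%
```

E far above its null says the probe concentrates on the granule; the
docking run recovers the generator's realized long-lived share (40.0%
for this seed) from the rendered movie alone.

The same chains are available from the shell, e.g.

```
tirfgran simulate --kind docking --config cfg.yml --out run/
tirfgran dock --movie run/movie.tif --out run/dock/
```

Every command writes a `manifest.json` recording inputs, parameters,
version and seed.

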