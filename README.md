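# filoquant

Absolute quantitation of HaloTag-labeled myosin 10 (Myo10) in cells and
filopodia from epifluorescence microscopy, calibrated by SDS-PAGE
densitometry.

Filopodia are thin, finger-like protrusions built on parallel fascin-actin
bundles, and Myo10 is the motor that builds them and rides to their tips.
Knowing the *absolute* number of Myo10 molecules in a cell, a filopodium,
or a tip punctum — not just relative intensities — is what lets one reason
about stoichiometry: how many motors per actin filament, whether the tip
outnumbers its accessible actin-binding sites, and how accumulation relates
to elongation speed. This package implements that measurement pipeline for
cell biologists and quantitative microscopists, exercised end to end on
synthetic data with known ground truth.

## The measurement model

**Gel calibration.** A dilution series of a 61 kDa HaloTag standard protein
(masses 1.25–15 ng) defines a through-origin standard curve
signal = *a*·mass. A lysate lane of *N* cells then gives the mean molecules
per transfected cell:

⟨m⟩ = (signal/*a*) · 10⁻⁹/MW · N_A / ε / (*N*·*f*)

with labeling efficiency ε = 0.90 and transfection fraction *f*. The slope's
95% CI (Student t, df = lanes − 1) is propagated multiplicatively to every
downstream molecule estimate.

**Fluorescence scale.** For a calibration set of *n* imaged cells whose
background-corrected total-cell signal sums to *I_n*, any region of interest
with signal *I*_ROI holds

r = *n* · ⟨m⟩ · *I*_ROI / *I_n*  molecules.

**Segmentation.** Background is removed by the mean of a 56×56 px square
near the cell (or a 50 px rolling ball for live snapshots). The Myo10
channel thresholds to a *total-cell mask*; the phalloidin channel, after
erosion and opening, gives a *cell-body mask*; their set difference is the
*filopodia mask*, whose 8-connected components (pixels joined through at
most two orthogonal hops) are the Myo10 puncta.

**Tip geometry.** A filopodium is a cylinder of radius 0.1 µm around a
30-filament bundle with 16 surface filaments; 4 of the 13 monomers per
helical turn (axial rise 2.7 nm) are sterically accessible to Myo10, giving
an accessible-actin concentration of ~96 µM independent of length. A
membrane budget (hemispherical cap 2πr² plus wall 2πrL, divided by a
per-motor footprint) bounds how many motors the tip membrane can dock.

**Lifecycle statistics.** Per-frame detections are linked (0.5 µm
frame-to-frame, gap closing ≤ 2 frames within 1 µm), start sizes are the
mean of the first two frames, accumulation is a one-sample t-test on each
trajectory's final delta, and speed–molecule association is Spearman rank
correlation of pooled gap-aware instantaneous speeds.

## Worked example

Simulate a gel, calibrate it, and interrogate a tip punctum:

```sh
$ filoquant --out-dir demo --seed 1 simulate gel --mean-molecules 1e6
wrote demo/lanes.csv
$ filoquant --out-dir demo calibrate --lanes demo/lanes.csv
slope = 24.32 signal/ng (SE 0)
mean molecules per transfected cell = 1e+06 (95% CI 1e+06 – 1e+06)
$ filoquant tips --molecules 788 --length-um 0.5
local concentration = 83.3 uM
accessible actin    = 96.4 uM
class = below_actin
```

The noiseless synthetic gel round-trips ⟨m⟩ = 10⁶ exactly; a 788-molecule
punctum spread over 0.5 µm sits at 83 µM, just below the ~96 µM
accessible-actin ceiling, so it is classified `below_actin`.

The same from Python, on a rendered synthetic cell:

```python
import numpy as np
from filoquant import synthetic, quantify

myo10, phalloidin, truth = synthetic.make_cell_scene(rng_seed=3)
first = quantify.quantify_scene(myo10, phalloidin)
scale = quantify.FluorescenceScale(1, truth.total_molecules, first.cell_total_intensity)
result = quantify.quantify_scene(myo10, phalloidin, scale=scale)

print(round(result.cell_total_molecules))          # 805918  (truth: 805918)
print(round(result.percent_filopodial, 2))         # 5.28    (truth: 5.35)
print(len(result.filopodium_totals))               # 30 filopodia
print(round(np.median(list(result.filopodium_totals.values()))))  # 1094 molecules
```

The cell total is recovered to the displayed digit, 5.3% of Myo10 is
filopodial, and the median filopodium carries about a thousand motors —
hundreds of Myo10s per protrusion.

## Layout

- `filoquant.synthetic` — gel, scene, and trajectory generators with truth
- `filoquant.calibration` — standard curve, ⟨m⟩, slope-CI propagation
- `filoquant.quantify` — background, masks, puncta, molecule conversion
- `filoquant.rose` — 20-section angular profiles with bootstrap SEM
- `filoquant.tipmodels` — tip concentration, accessible actin, membrane budget
- `filoquant.tracks` — linking, delta traces, t-tests, speeds, trends
- `filoquant.config` / `filoquant.cli` — YAML config, pipeline, `filoquant` CLI

See `docs/methods.md` for assumptions, parameter choices, and limitations.
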