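# gcflow

Quantification of cytoskeletal dynamics in neuronal growth cones from
fluorescence time-lapse microscopy, for developmental neurobiologists
studying how microtubules and F-actin interact during neurite outgrowth
and axon specification.

During early polarization, a neuron's growth cones differ in how fast
their F-actin treadmills — polymerizing at the leading edge while
flowing retrogradely toward the cell body — and in how many growing
microtubule plus-ends (marked by EB3 "comets") they receive. This
package implements the measurement chain used to relate those
quantities per growth cone:

* **Treadmilling speed** — kymographs are drawn along a neurite
  (width 1, distance × time); a structure moving at constant speed *v*
  appears as a track of slope *v*, and the mean |slope| of retrograde
  tracks, converted by the spatial/temporal calibration, is the speed
  in µm/min. Both a manual-endpoint mode (exact arithmetic on clicked
  track ends) and an automatic estimator (orientation-scan + ridge
  refinement) are provided.
* **EB3 comet counts** — comets crossing a line at the growth-cone neck
  appear as distinct spots in the neck kymograph; difference-of-Gaussian
  filtering and prominence-thresholded local maxima count them.
* **Coverage** — the percentage of the reporter-covered growth-cone
  area occupied by EB3 signal, from thresholded max-projections.
* **Intensity tracing** — per-frame "mean" auto-threshold segmentation
  of the growth cone with intensity read-out from the original channel,
  over all 151 frames of a 5-min / 2-s acquisition.
* **Statistics** — standard-score (z) normalization, under which the
  least-squares slope equals Pearson's r; a nested-F linearity gate
  escalating to a second-order polynomial; two-tailed t, one-way ANOVA
  with Dunnett/Tukey post hoc.
* **Pyrene kinetics** — bulk actin-polymerization traces fitted to a
  lagged exponential saturation for plateau (Ymax) and half-time (t½).

Because such live-imaging recordings are essentially never deposited,
the package also ships a synthetic scene generator (speckle flow, 
Poisson comet traffic, diffuse marker, PSF + Poisson/Gaussian noise)
with complete ground truth, and every stage is validated by parameter
recovery. See `docs/methods.md` for models, conventions, and
limitations.

## Worked example

```python
import gcflow as g

# a synthetic five-neurite cell whose comet rate is proportional to its
# F-actin flow speed, imaged 5 min at 2 s/frame
cfg = g.correlated_cell_config(seed=11)
cell = g.analyze_cell(cfg)
for n in cell.neurites:
    print(f"{n.label}: {n.est_speed_um_min:.2f} um/min "
          f"(true {n.true_speed_um_min:.2f}), {n.comet_count} comets")
print("comet/treadmilling Pearson r =", round(cell.correlation["r"], 3))
```

prints

```
n1: 1.09 um/min (true 1.00), 5 comets
n2: 2.48 um/min (true 2.25), 8 comets
n3: 3.63 um/min (true 3.50), 13 comets
n4: 4.73 um/min (true 4.75), 23 comets
n5: 6.09 um/min (true 6.00), 17 comets
comet/treadmilling Pearson r = 0.845
```

Each line is one neurite: the automatically estimated treadmilling
speed tracks the configured ground truth within a few percent, comet
counts rise with the configured entry rate, and the cross-neurite
correlation between comet number and treadmilling speed — computed on
standard-score axes, where the fitted slope equals r — comes out
strongly positive, as it was built to be.

The same stages are scriptable from the shell (`gcflow simulate`,
`gcflow kymo`, `gcflow speed`, `gcflow comets`, `gcflow coverage`,
`gcflow intensity`, `gcflow stats`, `gcflow kinetics`, `gcflow run`),
and the numbered drivers under `analysis/` run each validation study
and write its table under `results/`:

```bash
python analysis/02_treadmilling_speed.py   # speed recovery, 1-6 um/min
python analysis/07_full_pipeline.py        # end-to-end correlation
```

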