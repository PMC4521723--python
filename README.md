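# onhmorph

In-vivo morphometry of the optic nerve head (ONH) and anterior lamina
cribrosa surface (ALCS) for longitudinal glaucoma studies.

In glaucoma, retinal ganglion cell axons are injured where they pass
through the lamina cribrosa — the collagenous mesh at the bottom of the
optic nerve head. Changes in the lamina's position, shape and pore
microarchitecture are measurable *in vivo* (OCT for the ONH, adaptive
optics imaging for the pores) and appear to precede the clinical standard
marker, retinal nerve fiber layer thinning. This package implements the
full measurement chain from manual image markups to change-onset
statistics, for researchers analysing such longitudinal primate or
clinical datasets (or validating methods on synthetic ones):

* **Geometry** (`onhmorph.geometry`) — total-least-squares BMO reference
  plane, direct least-squares BMO ellipse, thin-plate-spline ALCS surface
  h(u,v) = a₀ + a₁u + a₂v + Σ wᵢ·r²log r, and the scalar parameters:
  mean **ALCSD** (mean surface height over the BMO-ellipse interior,
  positive posterior), mean **RoC** (least-squares sphere radius of the
  surface within the ellipse, with a flat sentinel), and mean **MRW**
  (per-B-scan minimum BMO→ILM distance, averaged).
* **Pore morphometry** (`onhmorph.pores`) — 2D pore polygons lifted onto
  the surface; 3D area, moment elongation √(λ₁/λ₂), nearest-neighbour
  distance; equal-area central/peripheral regions and 60° sectors.
* **Spatial statistics** (`onhmorph.spatial`) — 3-bin maximal-separation
  clustering, Moran's I with permutation inference,
  I = (n/S₀)·Σwᵢⱼzᵢzⱼ/Σzᵢ², and the Mann–Whitney rank-sum test.
* **Longitudinal analysis** (`onhmorph.longitudinal`) — control-eye
  repeatability (CoR = 1.96·SD·√2, CoV = 100·SD/mean), first-change
  onset detection with a no-return rule, cumulative IOP difference
  (mmHg·days), dense-rank onset positions, Kaplan–Meier curves with
  log-rank sequencing, and fellow-eye agreement summaries.
* **Synthetic data** (`onhmorph.synth`) — ground-truthed marked eyes
  (spherical-cap lamina), pore fields (jittered hex lattice with
  controllable spatial clustering) and longitudinal studies, calibrated
  to published normal-eye and experimental-glaucoma summary statistics
  (bundled in `onhmorph.reference_data`).
* **Pipeline/CLI** (`onhmorph.pipeline`, `onhmorph` command) — per-study
  orchestration with YAML config, manifests and a human-readable report.

## Worked example

Generate a marked eye with known ground truth (ALCSD 200 μm, RoC 3 mm,
MRW 300 μm, 5 μm marking noise), fit it, then run change-onset detection
on a synthetic study:

```python
from onhmorph import (EyeTruth, synth_eye, fit_onh, StudyTruth,
                      synth_longitudinal_study, detect_first_change,
                      repeatability_stats)

eye = synth_eye(EyeTruth(alcsd_um=200, roc_mm=3.0, mrw_um=300, noise_um=5.0, seed=42))
fit = fit_onh(eye)
print(f"ALCSD {fit.params.alcsd:.1f} um, RoC {fit.params.roc:.2f} mm, "
      f"MRW {fit.params.mrw:.1f} um ({fit.params.n_bscans} B-scans)")

study = synth_longitudinal_study(StudyTruth(seed=42))
for p in ("alcsd", "mrw", "roc", "rnflt"):
    stats = repeatability_stats(study.control.values[p])
    rec = detect_first_change(study.eg.days, study.eg.values[p],
                              (stats.ci_low, stats.ci_high), parameter=p)
    print(f"{p:6s} control CoV {stats.cov:4.1f}%  first change day {rec.onset_day:.0f} "
          f"({rec.direction})")
```

prints

```
ALCSD 199.9 um, RoC 3.00 mm, MRW 299.1 um (48 B-scans)
alcsd  control CoV  3.7%  first change day 112 (increase)
mrw    control CoV  1.9%  first change day 168 (decrease)
roc    control CoV 15.6%  first change day 280 (decrease)
rnflt  control CoV  1.9%  first change day 336 (decrease)
```

The fitted parameters land within noise of the injected truth, and each
parameter's first sustained departure from the control eye's tolerance
interval (mean ± 1.96·SD) is recovered at its injected onset day —
ALCSD first, RNFLT last, the sequencing this methodology exists to
measure. The same machinery runs from the command line:

```bash
onhmorph synth study --seed 1 --out demo/
onhmorph run --input-dir demo/ --output-dir demo_out/
onhmorph report demo_out/
```

File formats (markup JSON, pore polygon JSON or mask images, long-format
study/IOP CSV) are documented in `onhmorph/io.py`; the scientific choices
and their rationale are in `docs/methods.md`.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's main results from scratch: the published-summary
arithmetic (fellow-eye ONH agreement, mean cumulative IOP difference,
means of per-eye extrema, dense-rank onset positions, repeatability
coefficients) from the bundled reference tables, the geometric recovery
of a ground-truthed synthetic eye at the given seed, and a five-eye
synthetic longitudinal study with first-change detection and
Kaplan–Meier/log-rank sequencing, printing a JSON summary and writing the
results file.
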