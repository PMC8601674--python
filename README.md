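# lungwater

Simulation, reconstruction and quantitation toolkit for proton-density
("lung water") MRI of the lungs, together with the cardiac functional
metrics and ordered-cohort statistics used to link myocardial energetics,
exercise reserve, and exercise-induced pulmonary congestion in heart
failure with preserved ejection fraction (HFpEF).

## The problem

Patients across the spectrum of diastolic dysfunction — from healthy
controls through type 2 diabetes and HFpEF to cardiac amyloidosis —
accumulate water in the lungs during even mild exercise. Detecting that
congestion non-invasively needs an MRI sequence whose lung signal is
*linear in tissue water content*, is fast enough to run immediately after
exercise, and tolerates exercise-induced motion. This package provides a
desk-scale digital laboratory for that measurement chain plus the
statistical layer used to analyse such a cohort:

- **`lungwater.signal`** — the spoiled gradient-echo steady state
  `S = PD·sin α·(1−E1)/(1−E1·cos α)·exp(−TE/T2*)`, `E1 = exp(−TR/T1)`,
  with a Bloch-equation simulator as an independent check. At the
  sequence's low flip angle (α = 5°) and ultrashort first echo, `S` is
  nearly T1-independent and proportional to proton density.
- **`lungwater.phantom`** — digital phantoms: a porous sponge mimetic of
  lung parenchyma with controllable water fill, and an analytic-ellipse
  axial thorax slice (lungs, heart, chest wall, optional pleural effusion)
  with a rigid-motion exercise model.
- **`lungwater.acquisition`** — golden-angle (137.5078°) radial-out
  multiecho k-space sampling, computed from exact ellipse Fourier
  transforms or direct non-uniform DFT of the sponge grid, with noise and
  time-resolved motion corruption.
- **`lungwater.reconstruction`** — Kaiser-Bessel gridding with
  angular-gap-aware density compensation (ramp or Pipe-Menon), 2× field-of-
  view oversampling with central cropping, TE→0 extrapolation across
  echoes, and a spoke-consistency filter that rejects motion-corrupted
  spokes by their k-space-center deviation from the running median.
- **`lungwater.quantitation`** — lung-ROI signal statistics, rest→stress
  absolute and percentage change, linear look-up-table display, and
  Bland-Altman agreement.
- **`lungwater.cardiac`** — peak diastolic filling rates from volume-time
  curves (mL/s or EDV/s), chamber volumetry (EDV/ESV/SV/EF, SV/ESV), rest/
  stress reserve deltas, and the saturation- and blood-corrected PCr/ATP
  ratio from ³¹P spectroscopy amplitudes.
- **`lungwater.stats` / `lungwater.cohort`** — Jonckheere-Terpstra
  ordered-trend test (exact, permutation, tie-corrected normal), Wilcoxon
  signed-rank, Kruskal-Wallis with Dunn post hoc, Pearson/linear
  regression, Preacher-Hayes single-mediator regression with
  bias-corrected bootstrap of the indirect effect `a·b`, and a synthetic
  cohort generator over the ordered groups control < T2D < HFpEF <
  amyloid (default sizes 11/9/14/9).
- **`lungwater.validation`** — brute-force reference implementations
  (explicit-DFT least-squares and conjugate-phase reconstruction, JT
  permutation enumeration, Wilcoxon 2ⁿ sign enumeration) used to verify
  the fast paths.

## Worked example

Simulate a rest/stress pair of thorax slices whose lung water fraction
rises from 0.20 to 0.22 (a true +10% change), acquire 200 golden-angle
spokes with the 5° multiecho UTE model, reconstruct by gridding, and
quantify the lung ROI:

```python
import numpy as np
from lungwater import (SequenceParams, make_thorax, sample_kspace,
                       trajectory_for_grid, ReconConfig, reconstruct_pd)
from lungwater.quantitation import lung_roi_from_slice, lung_water_change

seq, cfg = SequenceParams(), ReconConfig(grid_size_px=64)
maps = {}
for w in (0.20, 0.22):
    slice_ = make_thorax(lung_water_fraction=w, seed=2)
    traj = trajectory_for_grid(200, 64, slice_.fov_mm)
    maps[w] = reconstruct_pd(sample_kspace(slice_, seq, traj), cfg)

roi = lung_roi_from_slice(make_thorax(0.20, seed=2), 64)
res = lung_water_change(maps[0.20], maps[0.22], roi, roi)
print(f"rest {res.rest_signal:.1f} AU, stress {res.stress_signal:.1f} AU, "
      f"change {res.percent_change:+.2f}%")
```

prints

```
rest 4.4 AU, stress 4.9 AU, change +9.11%
```

— the integrated lung signal tracks the 10% water increase to within the
linearity of the chain. The same scan from the shell:

```bash
lungwater simulate-signal --flip 5 --tr 5 --te 0.1,1.2,2.3 --water-grid 0.05:0.5:10
# pearson_r=0.9994 slope=0.0352 max_dev=0.0171
```

showing the closed-form signal is linear in water fraction to r = 0.9994
over the physiologic range even though T1 and T2* co-vary with water
content.

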