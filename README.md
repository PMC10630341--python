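# lenspol

Lens-less polarization-sensitive ptychography: simulation, phase retrieval
and quantitative birefringence mapping.

## What it does

Birefringence — the polarization-dependent refractive index of ordered
materials such as collagen, myocardium, or monosodium-urate (gout)
crystals — is usually imaged with a polarized-light microscope, at the
cost of rotating polarizers and a small field of view.  A lens-less
alternative places the sample directly over an image sensor: a
programmable LED array provides angle-varied, circularly polarized
illumination; a random binary amplitude mask modulates the transmitted
wave; and a division-of-focal-plane (DoFP) polarization camera records
each frame through a 2×2 mosaic of micro-polarizers (0°/45°/90°/135°).
From one frame per LED, ptychographic phase retrieval recovers the
complex field of every polarization channel over the whole sensor, and
Jones-calculus inversion turns the four channel intensities into
quantitative maps of phase retardance δ and optic-axis orientation θ.

`lenspol` implements the full chain — forward simulator, DoFP
demosaicing, ePIE-style reconstruction engine, and birefringence
inversion — for researchers in computational imaging and quantitative
polarization microscopy.

The core algebra: with circular input of intensity I, a thin retarder
(δ, θ) and an analyzer at ψ give

    (I_0, I_45, I_90, I_135) = I/2 (1 − sinδ sin2θ, 1 + sinδ cos2θ,
                                    1 + sinδ sin2θ, 1 − sinδ cos2θ)

    Q1 = (I_90 − I_0)/(I_90 + I_0),  Q2 = (I_45 − I_135)/(I_45 + I_135)
    δ = asin √(Q1² + Q2²),           θ = ½ atan2(Q1, Q2)

See `docs/methods.md` for the model, algorithms and design choices.

## Worked example

```python
import numpy as np
from lenspol import (SystemGeometry, scenes, capture_stack,
                     run_pipeline, ReconSettings)

# 128x128 px scene at the 3.45 um sensor pitch, full 9x9 LED array
geometry = SystemGeometry(led_grid=(9, 9), sensor_px=(128, 128))
needle = scenes.needle_crystal((128, 128), axis_angle=np.deg2rad(15),
                               delta0=0.272, length_px=60, width_px=10)
mask = scenes.random_binary_mask((128, 128), feature_px=8, seed=1)

stack = capture_stack(needle, mask, geometry)        # 81 mosaicked frames
result = run_pipeline(stack, mask,
                      settings=ReconSettings(iterations=20),
                      demosaic_method="np")

inside = needle.delta > 0
print(f"retardance  : {np.median(result.delta[inside]):.3f} rad")
print(f"orientation : {np.degrees(np.median(result.theta[inside])):.1f} deg")
```

Output:

```
retardance  : 0.246 rad
orientation : 12.9 deg
```

The needle was generated with δ = 0.272 rad and θ = 15°: from mosaicked
raw frames only, the median over every needle pixel (edges included)
recovers the retardance within ~10% and the orientation within ~2°;
restricting the statistics to the needle interior tightens both (the
rotation-series benchmark scores R² ≈ 0.999 against the true angles).

A command-line interface wraps the same chain:

```
lenspol simulate --scene needle --shape 128 --out stack.tif
lenspol birefringence --stack stack.tif --iterations 20 --out maps/
```

writing retardance/orientation/phase maps as float TIFF and a pseudo-color
render (hue = orientation, brightness = retardance) as PNG.

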