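# gastroflow

Quantitative analysis of **gastric motility and emptying** from dynamic
MRI, for physiologists and imaging scientists working with real-time
(cine) stomach acquisitions.

After a test meal labeled with a T1 contrast agent (manganese(II)
gluconate), the gastric content is bright on T1-weighted images. Two
acquisitions then capture stomach function:

* **multi-slice 2D+t real-time series** through the antrum (three
  sagittal slices, ~6.24 frames/s) show the peristaltic contraction wave
  as a rhythmic modulation of the lumen cross-sectional area;
* **static 3D volumes** at successive timepoints measure the gastric
  content volume (GCV) as it empties.

gastroflow turns segmented masks (or its own threshold segmentation of
bright-lumen images) into the standard motility and emptying metrics:

| metric | definition |
|---|---|
| dominant frequency | FFT peak of the area signal in 0.03–0.07 Hz (1.8–4.2 cpm), valid when the dominance factor (peak / mean in-band amplitude) ≥ 2.0; timepoint mean requires ≥ 2 of 3 valid slices |
| occlusion | 100 × (1 − area / reference), reference = median of the top-10% largest areas; clipped at 0, 100% = complete closure |
| propagation distance | 3 × thickness + 2 × gap for the three-slice stack (mm) |
| apparent speed | frequency/60 × propagation distance (mm/s), cross-checked by an inter-slice cross-correlation delay estimate |
| emptying rate | −dV/dt by least squares over an explicit window (mL/min) |
| half-life | ln(2)/k (first-order fit of ln V on t) or c₀/(2k) (zero-order fit of V on t) |

Because clinical scanner data cannot be shipped, the package includes a
**synthetic phantom generator**: traveling-wave area signals, rendered
2D+t bright-lumen image/mask stacks, 3D volumetry spheres, and emptying
curves — all with known ground truth and bit-reproducible from a seed.
See `docs/methods.md` for the model and its assumptions.

## Worked example

```python
from gastroflow import (
    PhantomSpec, EmptyingSpec, SliceGeometry,
    generate_area_signals, generate_emptying_series,
    analyze_timepoint, fit_emptying,
)

geometry = SliceGeometry(slice_thickness=5.0, distance_factor=3.0)
spec = PhantomSpec(true_frequency=2.0, wave_speed=1.7, occlusion_depth=0.5,
                   geometry=geometry, seed=42)
report = analyze_timepoint(generate_area_signals(spec), geometry)

volumes = generate_emptying_series(EmptyingSpec(
    model_order="first", rate_constant=0.0469, initial_volume=290.0,
    noise_sd=5.0, seed=42))
fit = fit_emptying(volumes, "first")
```

prints (via the fields shown):

```
valid slices        : 3/3
mean frequency      : 2.00 cpm
mean occlusion      : slice 1: 19.6%, slice 2: 19.7%, slice 3: 19.4%
propagation distance: 45 mm
apparent speed      : 1.50 mm/s
crosscorr speed     : 1.92 mm/s
emptying k          : 0.0478 per min
half-life           : 14.51 min
```

Reading this: all three slices carry a valid 2.0 cpm contraction
frequency (the phantom's truth). Mean occlusion ≈ 20% is consistent with
a depth-0.5 pulsatile wave that occludes fully only at its peak. The
45 mm three-slice span at 2 cpm gives an apparent speed of 1.50 mm/s;
the cross-correlation delay estimate (1.92 mm/s) brackets the true
1.7 mm/s — both carry the documented geometric bias of the slice-span
convention. The noisy exponential emptying series (true k = 0.0469/min,
i.e. t½ = 14.78 min) is recovered as t½ = 14.51 min.

## Command line

```bash
gastroflow simulate --frequency 3 --occlusion-depth 0.5 --out-dir sim/
gastroflow segment sim/slice1_image.nrrd sim/slice2_image.nrrd \
    sim/slice3_image.nrrd --out-dir seg/
gastroflow motility seg/areas.csv --distance-factor 3.0 --out-dir mot/
gastroflow volumetry sim/volumes.csv --model-order first --out fit.json
gastroflow run config.yaml          # end-to-end with provenance + report
```

`run` persists its configuration and a JSON report embedding the config
hash; identical configuration and seed reproduce byte-identical outputs.
Slices where no stomach is found are reported as dropouts, never
silently dropped (exit status 2 flags partial success). Stage outputs
are the next stage's inputs, so expert-corrected masks can replace the
automatic ones and the downstream stages rerun unchanged.

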