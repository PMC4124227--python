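# markalign

Machine-vision chamber positioning for multi-chamber microfluidic time-lapse
monitoring: detection of a three-circle alignment mark (circle triad) in
microscopy images, and closed-loop xy-stage realignment driving the chamber
position error below a 3-pixel tolerance. A virtual stage simulator and a
synthetic chamber-view renderer allow the whole alignment workflow — including
multi-scan drift experiments — to be exercised and tested without hardware.

## Pipeline

1. **image_core** — RGB→gray conversion (channel mean) and Gaussian lowpass
   filtering with a `D × D` mask (unit-sum by default; the literal
   `1/(2Nπσ²)` form is available behind `normalize=False`).
2. **edge_detect** — Sobel gradients (`|Sx|+|Sy|` magnitude, 45°-quantized
   directions), non-maximum suppression along the quantized gradient
   direction, and Zhang–Suen-style thinning to one-pixel-wide edges.
3. **template_match** — tri-valued circle templates (white circle, optional
   one-pixel gray boundary rings, excluded black) and the normalized
   edge-match map `C(x, y) ∈ [0, 1]`; the three strongest well-separated
   peaks locate one mark.
4. **mark_pose** — triad role assignment (upper-left / right / lower),
   reference position, orientation estimate, and the position error `E`
   (pixels and micrometers at 0.94 µm/px).
5. **stage_sim** — virtual motorized stage (believed vs. true position, with
   per-move noise, pitch bias, and per-scan drift), 4×8 chamber geometry,
   serpentine scan paths, and camera-view capture via the renderer.
6. **align_control** — closed-loop realignment (capture → detect → corrective
   move until `E ≤ 3 px`), chamber-to-chamber distance updates, mark→chamber
   center imaging round trip, multi-scan runs, and the four-case error
   characterization experiment.
7. **synthetic_data** — anti-aliased rendering of marks at exact sub-pixel
   poses with ground truth, plus liquid-replacement frame sequences.
8. **liquid_trace** — chamber-ROI intensity traces, plateau normalization,
   exponential time-constant fitting and 90%-replacement-time readout.

## CLI

```sh
markalign render --out mark.png --truth truth.json --offset 6 -4 --seed 1
markalign detect mark.png --out pose.json --debug-dumps dumps/
markalign align --offset 40 -25 --seed 0
markalign scan --scans 5 --align --seed 0 --out records.csv
markalign scan --scans 5 --no-align --seed 0 --out drift.csv
markalign characterize --cases 1,2,3,4 --repeats 80 --out cases.csv
markalign trace frames_dir/ --roi disc:23.5,23.5,12 --out trace.csv
```

All commands accept `--config path.yaml` (nested keys under `gaussian`,
`edge`, `template`, `stage`, `geometry`, `alignment`, `render`; unknown keys
are rejected). Outputs are deterministic under a fixed seed.

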