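# blinktrack

Event-based eye-blink detection and face tracking for asynchronous
event-camera (silicon-retina) streams.

Conventional face detectors need frames and heavy trained models. An event
camera never produces frames — each pixel independently emits an event
`ev = (x, y, t, p)` with microsecond timestamp `t` and ON/OFF polarity `p`
whenever its log-luminance changes — but it captures facial *dynamics* that
frames blur away. The most distinctive of these is the eye blink: the
eyelid closes within ~100 ms and floods the eye region with ON events, then
reopens more slowly under a burst of mainly OFF events. That stereotyped
temporal signature is stable across people, which makes a blink a
detector-free beacon for "two eyes of a face are here". `blinktrack`
implements the full event-driven pipeline around this idea, plus a
synthetic event-scene simulator with ground truth so the whole method can
be developed and tested without camera recordings.

## Method

Every incoming event updates, per spatial tile and polarity, a decaying
activity trace

    A_p(t_i) = A_p(t_last) · exp(−(t_i − t_last)/τ) + 1/scale,     τ = 50 ms,

where `scale` normalizes the event flux of nearer (larger) faces. The
sensor plane is covered by an n × n tile grid (n = 16 → 19 × 15 px tiles
at 304 × 240) overlapped with a half-shifted (n−1) × (n−1) grid so that an
eye straddling one grid's boundary sits near a tile center of the other.

A canonical blink template `B_ON(t), B_OFF(t)` over a T = 250 ms window is
the pointwise average of the activity traces of M annotated blink windows.
Because activity samples exist only at event times, each tile is scored by
the sparse cross-correlation

    C = α Σ_i A_ON(t_i) B_ON(t_i − t_k) + (1−α) Σ_i A_OFF(t_i) B_OFF(t_i − t_k),

with window origin `t_k = t_now − T` and α = 2/3 (ON weighted double — the
closure burst dominates). A tile is only scored once its windowed event
count reaches a gate derived from the template's expected count N, and
emits a *blink candidate* `eb = (r, c, t)` when C clears a calibrated
threshold. Candidates from the two grids are fused, then validated in
pairs: two eyes must blink within ΔT_max = 50 ms of each other, with
horizontal separation in [one tile width, W/2] and vertical offset below
H/5 (all spatial bounds scaled by the face's scale when a tracked face is
nearby).

Each validated detection either starts or corrects a face track: two
bivariate-Gaussian eye trackers scoring every event with the normal
density p(u) = (2π)^(−1) |Σ|^(−1/2) exp(−½ (u−μ)ᵀ Σ⁻¹ (u−μ)), updated by
exponential blending of their gated events. Blink detections re-initialize
the trackers at the detected eye positions — drift correction for free,
at physiologically guaranteed intervals — and refresh the scale factor
(eye distance / 95 px reference). Tracking quality is measured as the
face-box center deviation normalized by the box width.

## Worked example

```bash
python examples/02_detect_blinks.py
```

```
scene: 312150 events over 60 s, 10 true blinks
blinks detected:  100%   false positives: 0
  detection at t=3.06 s, eyes (66.0, 127.0) / (161.0, 127.0)
  detection at t=8.85 s, eyes (66.0, 127.0) / (161.0, 127.0)
  ...
```

A static face at the 95 px reference eye distance blinks ten times during
60 s while the sensor sees 5,000 background events per second; every blink
is recovered with zero false alarms, and each detection localizes both
eyes to the correct 19 × 15 px tile (positions are tile centers). The
other examples build a template from scratch (`01`), quantify what blink
drift-correction buys on a translating face (`03` — mean normalized error
0.033 with corrections, 0.041 and a lost track without), and recover face
scale across a four-fold eye-distance sweep (`04` — scales 1.0 / 2.0 /
0.502 against true 1.0 / 2.0 / 0.5).

The same machinery is scriptable from the shell:

```bash
blinktrack simulate scene.json --events events.csv --truth truth.json
blinktrack build-model --synthetic-m 120 --condition indoor --out model.json
blinktrack track events.csv --model model.json --out-tracks tracks.csv \
    --out-detections detections.json
blinktrack evaluate --detections detections.json --tracks tracks.csv \
    --truth truth.json --out metrics.json
```

## Layout

- `src/blinktrack/` — library: `events` (I/O), `activity`, `tiling`,
  `blink_model`, `correlation`, `pairing`, `tracking`, `pipeline`,
  `synth` (simulator), `scenes` (benchmark scenarios), `cli`.
- `src/blinktrack/models/` — two shipped synthetic-trained templates
  (indoor/outdoor ON:OFF ratios); regenerate with
  `python scripts/build_default_models.py`.
- `examples/` — one narrative script per capability.
- `docs/methods.md` — model assumptions, parameter choices, limitations.
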