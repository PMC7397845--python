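# Methods

## Signal model

An event camera reports asynchronous per-pixel change events
`ev = (x, y, t, p)`; only these change events are consumed (absolute
gray-level exposure events of ATIS-class sensors are out of scope).
Timestamps are integer microseconds, coordinates 0-based with the origin
at the top-left and y growing downward; loaders enforce time order and
sensor bounds. A human blink appears in this stream as an ON-event burst
while the eyelid closes (~100 ms) followed by a slower, OFF-dominant burst
while it reopens, the whole episode fitting a 250 ms window. Blinks recur
every few seconds (roughly 3–30 per minute depending on activity), which
is what makes them usable both for detection and for periodic tracker
correction.

## Activity, tiles and the blink template

Per tile and polarity the package maintains the exponentially decaying
activity `A_p(t) = A_p(t_last) exp(−Δt/τ) + 1/scale` with its own
last-event clock per polarity. τ defaults to 50 ms: long enough that a
whole closure burst is visible in one value, short enough that the trace
relaxes between blinks. The increment `1/scale` makes the trace amplitude
approximately invariant to face distance once a face's scale factor is
known; scale changes never rescale already-buffered history (the recursion
stays an exact incremental form of the per-event exponential sum, which
the tests verify against a brute-force oracle at 1e−9 relative
tolerance).

Two overlapping grids (16 × 16 and the half-shifted 15 × 15) bound the
quantization: any point on the sensor lies within a quarter tile of some
tile center of one grid. Each tile buffers its trailing 250 ms of events
together with the activity sample taken just after each increment, so the
correlation stage never recomputes decays; pruning is lazy (on update),
keeping per-event cost proportional to evictions.

The blink template is the pointwise mean of the per-blink activity traces
of M annotated windows, sampled on a uniform 1 ms grid and read back by
linear interpolation (1 ms ≪ τ, so interpolation error is negligible);
identical training blinks reproduce the single-blink curve to double
precision, and the mean is always inside the pointwise min/max envelope of
its inputs. The template also stores `n_events`, the floor of the mean
in-window event count — exposed as the per-window reading of the
"events per unit time, normalized by scale" quantity — plus the calibrated
correlation threshold and the reference eye distance (95 px) that defines
scale = 1. Indoor and outdoor templates are kept separate because real
sensors' ON:OFF balance shifts with lighting; the shipped models encode
this as 2:1 vs. 1.4:1 ON:OFF ratios in their synthetic training data.

## Candidate emission: count gate and threshold

A tile is scored only when its windowed event count reaches
`ceil(gate_fraction · n_events · scale)`. `gate_fraction = 0.12` is
calibrated against the simulator for the worst admissible attenuation: an
eye straddling both grids' tile boundaries keeps roughly half of its
events in its best tile, and a face at half the reference scale — the
closest operating distance before any face is tracked supplies its true
scale — emits a quarter of the nominal count (area scaling), compounding
to ~12.5%. Background noise at the benchmark's 5,000 ev/s leaves a tile
with only ~5 window events, an order of magnitude under the gate, so the
gate alone suppresses noise scoring entirely.

The correlation evaluates a single lag per triggering event, pinning the
template origin to the window start `t_k = t_now − T`: the score therefore
peaks when a complete blink fills the window, and no lag sweep is needed.
The emission threshold is set at model-build time to 2% of the weakest
training blink's self-score (its own buffer correlated against the final
template at the aligned lag). The 2% margin absorbs the same worst-case
attenuations as the gate — amplitude and count both shrink with tile
splitting and scale, quadratically in their product — while remaining
orders of magnitude above anything a sub-gate tile could score. The
threshold is stored in the model file; it is a specificity calibration
against the simulator, mirroring how a deployment would calibrate against
annotated recordings.

## Pairing, refractory and single-eye corrections

Candidate pairs are validated with ΔT_max = 50 ms, horizontal separation
in [one tile width, W/2] and vertical offset ≤ H/5, all spatial bounds
multiplied by the matched face's scale. The one-tile minimum separation
exists because a single eye can fire both overlapping grids; without it a
blink would pair with its own duplicate. Cross-grid duplicates (within one
tile diagonal and 10 ms) merge to the highest score before pairing, and
valid pairs are consumed greedily in increasing (|Δt|, Δx) order, making
the output independent of candidate arrival order for distinct gaps.

A tile stays above threshold for most of a blink, so one physiological
blink would otherwise produce dozens of detections; each face therefore
has a 400 ms refractory (≥ the window length) after an applied detection.
A candidate that expires unpaired inside an active face's eye gate is
treated as a single-eye blink (pose variation with one eye occluded) and
corrects only that tracker, never spawning a face.

## Trackers, scale and the face lifecycle

Eye trackers are bivariate normals updated by exponential blending
(η_μ = 0.05, η_Σ = 0.01) of events assigned by highest density within a
squared-Mahalanobis gate of 9 (≈3σ). Σ's eigenvalues are clamped to
[1, 256] px² — the floor for numerical conditioning, the 16 px-std cap so
that diffuse background activity cannot inflate a tracker into a
sensor-wide attractor; under heavy uniform noise trackers still wander
between corrections, and it is precisely the blink corrections that keep
them honest. A matched detection re-initializes both eye trackers (mean
and covariance) at the detected positions — corrections are
re-initializations, not nudges — and refreshes the face scale from the
detected eye distance; scale is deliberately *not* inferred from live
tracker separation, which noise would corrupt. A face with no eye events
for 2 s and no blink for 10 s is flagged lost; a later matching blink
revives it.

The face box used for evaluation is an anthropometric convention: width
2.2× and height 2.8× the eye distance, eyes at 35% of the box height. The
tracking metric is the box-center deviation divided by the box width,
making errors comparable across face sizes.

## The simulator and what passing tests mean

The generator emulates the phenomenology, not the optics: Poisson event
counts under raised-cosine ON/OFF envelopes (600 expected events per eye
per blink at scale 1, scaling with scale²), Gaussian spatial spread of
0.4 tile per axis (scaled), face-outline motion events proportional to
speed, uniform background noise, and whole-scene rate bursts. A face is a
piecewise-linear center trajectory with a (possibly time-varying) eye
distance and optional head roll. Everything derives from one seeded
generator, so scenes are exactly reproducible.

Benchmark scenes (`blinktrack.scenes`) fix the study conditions: a 60 s
static face with ten blinks under 5,000 ev/s noise for recall/specificity;
a 20 s, 50 px translation with 5 s blinks — noise-free, to isolate the
correction pathway (with corrections disabled the face starves, goes lost
after the 10 s blink-silence limit, and its frozen track accrues error);
and a 28 s approach/recede sweep probing eye distances of 95, 190 and
47.5 px. The sweep carries blinks *during* the distance ramps because the
pairing bounds scale with the last known face scale — a fresh 190 px eye
pair can never pass the unscaled W/2 = 152 px bound, exactly as a real
subject approaching a camera is re-detected incrementally. At the probed
distances the eyes are placed on tile centers (detections quantize to
tile centers), the closest phase with a slight head roll since 47.5 px
cannot align both eyes to one grid's 19 px center lattice.

What these passes do **not** show: real eyelid kinematics (no saccades,
partial blinks, eyebrow motion), sensor non-idealities (refractory pixels,
hot pixels, lighting-dependent ON/OFF imbalance beyond the fixed ratios),
or textured moving backgrounds. The calibrated threshold and gate would
need re-calibration against annotated recordings for a real camera.

## Numerical and degenerate-input choices

Equal timestamps are legal (no decay between them); ON and OFF decay from
their own last event times. Empty streams are valid inputs everywhere and
produce empty outputs. Density evaluation uses the closed-form 2 × 2
inverse with the clamped covariance, so it cannot go singular. Detection
ties (equal density) break deterministically on (face id, left-before-
right); pairing ties on the temporal gap break on horizontal distance and
then candidate order. The whole pipeline is deterministic given (stream,
model, config) — the CLI's outputs are byte-identical across runs.

## Known limitations

Scale inference needs both eyes, so sustained single-eye visibility keeps
the last known scale. Multiple faces closer than W/2 to each other can
cross-match detections. Heavy noise degrades tracker positions between
corrections (bounded by the blink rate, not by the noise level). The
simulator's envelope shapes and rates are design choices, stated above,
not fits to recordings.
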