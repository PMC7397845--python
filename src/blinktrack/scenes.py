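"""Canonical benchmark scenes for the detector and tracker.

Three reusable scenarios exercise the pipeline's headline behaviors; tests,
examples and the reproduction script all build them from here so the study
conditions are defined once.

``detection_scene``
    60 s, one static face at the reference eye distance (95 px, eyes on
    primary tile centers), ten blinks, 5,000 ev/s uniform background noise.
    Probes blink recall and false positives under heavy noise.

``drift_scene``
    20 s, the face translating 50 px, blinking every 5 s, no background
    noise: between blinks the eye trackers starve, so the scene isolates
    the drift-correction pathway (and, with corrections disabled, the
    lost-face endgame).

``scale_sweep_scene``
    28 s approach/recede sweep of the inter-eye distance 95 -> 190 -> 47.5 px
    with blinks throughout, emulating a subject walking toward and away
    from the camera; the three probed distances place the eyes on tile
    centers (detections quantize to tile centers), the closest phase with a
    slight head roll so each eye aligns with one grid.
"""

from __future__ import annotations

from .synth import FaceSpec, SceneSpec

S = 1_000_000  # microseconds per second

REFERENCE_EYES_Y = 127.0  # primary tile-row center for the default geometry


def detection_scene(seed: int = 0, duration_s: int = 60, noise_rate: float = 5000.0,
                    n_blinks: int = 10) -> SceneSpec:
    blink_times = [int((3 + 5.8 * k) * S) for k in range(n_blinks)]
    if blink_times and blink_times[-1] + 250_000 > duration_s * S:
        raise ValueError("blinks do not fit in the scene duration")
    return SceneSpec(
        duration_us=duration_s * S,
        faces=[
            FaceSpec(
                trajectory=[(0, 113.5, REFERENCE_EYES_Y),
                            (duration_s * S, 113.5, REFERENCE_EYES_Y)],
                eye_distance=95.0,
                blink_times=blink_times,
            )
        ],
        noise_rate=noise_rate,
        seed=seed,
    )


def drift_scene(seed: int = 0) -> SceneSpec:
    return SceneSpec(
        duration_us=20 * S,
        faces=[
            FaceSpec(
                trajectory=[(0, 120.0, REFERENCE_EYES_Y), (20 * S, 170.0, REFERENCE_EYES_Y)],
                eye_distance=95.0,
                blink_times=[2 * S, 7 * S, 12 * S, 17 * S],
            )
        ],
        noise_rate=0.0,
        seed=seed,
    )


#: End times (s) of the three constant-distance phases of the scale sweep,
#: at which the recovered scale should read 1.0, 2.0 and 0.5.
SCALE_PROBE_TIMES_S = (3.9, 11.9, 27.9)
SCALE_PROBE_TRUTH = (1.0, 2.0, 0.5)


def scale_sweep_scene(seed: int = 0) -> SceneSpec:
    return SceneSpec(
        duration_us=28 * S,
        faces=[
            FaceSpec(
                trajectory=[(0, 113.5, 127.0), (4 * S, 113.5, 127.0),
                            (8 * S, 123.0, 127.0), (12 * S, 123.0, 127.0),
                            (18 * S, 89.5, 123.563), (28 * S, 89.5, 123.563)],
                eye_distance=[(0, 95.0), (4 * S, 95.0), (8 * S, 190.0),
                              (12 * S, 190.0), (18 * S, 47.5), (28 * S, 47.5)],
                # head roll in the closest phase aligns each eye with a tile
                # center of one grid (47.5 px cannot align both eyes to one
                # grid's centers, which sit 19 px apart)
                tilt=[(0, 0.0), (12 * S, 0.0), (18 * S, -0.1452), (28 * S, -0.1452)],
                blink_times=[2 * S, 6 * S, 10 * S, 14 * S,
                             16 * S + 500_000, 17 * S + 600_000, 20 * S, 24 * S],
            )
        ],
        noise_rate=1000.0,
        seed=seed,
    )


def scale_at(result, t_s: float) -> float | None:
    """Face scale from the last track sample at or before ``t_s`` seconds."""
    best = None
    for s in result.tracks:
        if s.t <= t_s * S:
            best = s.scale
    return best
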