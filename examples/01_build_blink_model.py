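"""Build a blink template from annotated blink windows.

Simulates 120 single-eye blink windows (the synthetic stand-in for manual
annotation), averages their ON/OFF activity traces into a template, and
calibrates the candidate threshold from the training blinks' self-scores.
"""

import numpy as np

from blinktrack import build_model, calibrate_threshold, make_annotated_blinks

rng = np.random.default_rng(7)
blinks = make_annotated_blinks(120, condition="indoor", rng=rng)
model = build_model(blinks)
model.threshold = calibrate_threshold(blinks, model)

peak_on = model.grid_times[np.argmax(model.b_on)] / 1000.0
peak_off = model.grid_times[np.argmax(model.b_off)] / 1000.0
print(f"blinks averaged:      {model.m_blinks}")
print(f"expected event count: {model.n_events} per 250 ms window (gates scoring)")
print(f"ON template peak:     {model.b_on.max():.1f} at {peak_on:.0f} ms "
      "(eyelid closure)")
print(f"OFF template peak:    {model.b_off.max():.1f} at {peak_off:.0f} ms "
      "(slower reopening)")
print(f"candidate threshold:  {model.threshold:.3g} (correlation score)")
# The ON peak precedes the OFF peak because closing the eyelid brightens
# pixels (ON burst within ~100 ms) while reopening darkens them more slowly.
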