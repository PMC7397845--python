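"""Regenerate the shipped synthetic-trained blink templates.

Run from the repository root:

    python scripts/build_default_models.py

Writes ``src/blinktrack/models/synthetic_{indoor,outdoor}.json``: each is
built from 120 simulated annotated blinks (six synthetic subjects, +-20%
envelope jitter) with the candidate threshold calibrated from the training
blinks' self-scores. These files are synthetic stand-ins for templates
trained on recorded data.
"""

from pathlib import Path

from blinktrack.blink_model import save_model
from blinktrack.synth import train_default_model

OUT_DIR = Path(__file__).resolve().parent.parent / "src" / "blinktrack" / "models"


def main() -> None:
    OUT_DIR.mkdir(parents=True, exist_ok=True)
    for condition in ("indoor", "outdoor"):
        model = train_default_model(condition=condition, m=120, seed=7)
        path = OUT_DIR / f"synthetic_{condition}.json"
        save_model(model, path)
        print(
            f"{path.name}: m_blinks={model.m_blinks} n_events={model.n_events} "
            f"threshold={model.threshold:.4g}"
        )


if __name__ == "__main__":
    main()
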