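"""Shared plumbing for the numbered analysis drivers."""

from pathlib import Path

from camwound.pipeline import simulate_input_bundle

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
BUNDLE = RESULTS / "synthetic_inputs"
SEED = 0


def ensure_bundle() -> Path:
    """Generate the synthetic input bundle if it is not there yet."""
    config = BUNDLE / "config.yaml"
    if not config.exists():
        simulate_input_bundle(BUNDLE, seed=SEED, n_genes=400)
    return config
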