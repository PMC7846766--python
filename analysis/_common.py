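"""Shared plumbing for the numbered analysis drivers."""

from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"


def ensure_inputs(seed: int = 1) -> Path:
    """Simulate the full synthetic input set if not already on disk."""
    from silencerscape.simulate import simulate_full

    inputs = SCRATCH / f"synthetic_seed{seed}"
    if not (inputs / "manifest.json").exists():
        print(f"generating synthetic inputs under {inputs} (seed {seed})")
        simulate_full(inputs, seed=seed)
    return inputs


def results_dir() -> Path:
    RESULTS.mkdir(exist_ok=True)
    return RESULTS
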