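"""Shared constants for the analysis scripts: one seed, one dataset."""

from pathlib import Path

from basinrates.pipeline import RunConfig
from basinrates.simulate import SimulationConfig

SEED = 11
ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results" / "analysis"


def run_config(**kw) -> RunConfig:
    """The study's default run configuration (synthetic data, seed fixed)."""
    return RunConfig(simulate=SimulationConfig(seed=SEED), seed=SEED, **kw)
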