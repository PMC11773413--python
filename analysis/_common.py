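"""Shared configuration for the analysis scripts.

All drivers work on the same deterministic simulated experiments so their
outputs are mutually consistent; heavy intermediate data goes to scratch/,
small result tables to results/.
"""

from pathlib import Path

from microlineage.simulate import SimConfig, SimDataset, simulate_experiment

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"

SEEDS = {"wt_3day": 42, "wt_1day": 43, "mutant_3day": 44}

CONFIGS = {
    "wt_3day": SimConfig(seed=SEEDS["wt_3day"]),
    "wt_1day": SimConfig(seed=SEEDS["wt_1day"], low_days=1),
    "mutant_3day": SimConfig(seed=SEEDS["mutant_3day"], mutant=True, n_colonies=18),
}


def get_dataset(condition: str = "wt_3day") -> SimDataset:
    return simulate_experiment(CONFIGS[condition])


def ensure_dirs() -> None:
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)
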