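"""Shared setup for the analysis drivers: one simulated study, normalized.

Each numbered script calls :func:`get_study` so it can be run standalone;
the simulation is cheap enough to recompute (~1 s). Fixture files, when a
script writes them, go under ``scratch/`` (large, regenerable); result
tables go under ``results/``.
"""

from pathlib import Path

from immunecoex import (
    SimulationConfig,
    filter_low_expressed,
    normalize_log_cpm,
    simulate_counts,
    tmm_factors,
)

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"
STUDY_SEED = 17


def get_config(seed: int = STUDY_SEED) -> SimulationConfig:
    return SimulationConfig(seed=seed)


def get_study(seed: int = STUDY_SEED):
    """Simulate the default study and normalize it: (counts, truth, factors, expr)."""
    cm, truth = simulate_counts(get_config(seed))
    filt = filter_low_expressed(cm)
    nf = tmm_factors(filt)
    expr = normalize_log_cpm(filt, nf)
    return cm, truth, nf, expr


def outdir() -> Path:
    RESULTS.mkdir(exist_ok=True)
    return RESULTS
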