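"""Shared plumbing for the numbered analysis scripts."""
from pathlib import Path

from socdec import agents, io

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch" / "cohort"

COHORT_SEED = 20260921          # study geometry: 40 participants, 3 sessions
N_PARTICIPANTS = 40
SESSIONS = 3


def load_or_simulate(seed: int = COHORT_SEED):
    """Reuse the cohort written by 01_simulate.py when present, otherwise
    regenerate it deterministically from the same seed."""
    if SCRATCH.exists() and any(SCRATCH.glob("sub-*_trials.csv")):
        return io.read_dataset(SCRATCH)
    return agents.simulate_cohort(n=N_PARTICIPANTS, sessions=SESSIONS,
                                  seed=seed)
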