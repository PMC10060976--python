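"""Shared state for the numbered analysis drivers.

The study is fully synthetic and deterministic: every driver rebuilds the
same two-cohort design from a fixed seed, so the scripts can run in any
order.  Small summary tables go to ``results/``; bulky per-sample
matrices, when exported, go to ``scratch/`` (not part of the deliverable).
"""

from pathlib import Path

from chemonet import synthetic

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"

STUDY_SEED = 2026


def study_design() -> synthetic.SimulationDesign:
    """Default study conditions: two 200-sample cohorts, 2-log2 panel split."""
    return synthetic.SimulationDesign(seed=STUDY_SEED, n_cohorts=2)


def load_study():
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)
    return study_design(), synthetic.simulate_study(study_design())
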