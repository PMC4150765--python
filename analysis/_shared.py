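"""Shared setup for the numbered analysis drivers.

Every driver works on the same deterministic synthetic dataset (seed 11,
1000 promoters) so their outputs under results/ tell one consistent story.
"""

from __future__ import annotations

import os

from nucleoshift.phasing import promoter_windows_frame
from nucleoshift.simulate import SimulationConfig, SyntheticDataset, simulate_dataset

SEED = 11
RESULTS = os.path.join(os.path.dirname(__file__), "..", "results")


def study_config(**overrides) -> SimulationConfig:
    return SimulationConfig(n_genes=1000, seed=SEED, **overrides)


def get_dataset(**overrides) -> SyntheticDataset:
    return simulate_dataset(study_config(**overrides))


def windows_for(ds: SyntheticDataset):
    return promoter_windows_frame(ds.annotation)


def results_path(name: str) -> str:
    os.makedirs(RESULTS, exist_ok=True)
    return os.path.join(RESULTS, name)
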