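"""Shared configuration and file-layout helpers for the analysis scripts.

All scripts write under ``results/``; each numbered script consumes the
files of its predecessors, so the chain can be rerun from any stage.
"""

from __future__ import annotations

import json
from pathlib import Path

from cwrgap.geodata import VariableStack, read_raster
from cwrgap.synthetic import SimConfig

SEED = 1
N_SPECIES = 6
N_RECORDS = 200
N_EXPERTS = 5
EXPERT_NOISE_SD = 1.0

RESULTS = Path(__file__).resolve().parent.parent / "results"
WORLD_DIR = RESULTS / "world"
STACK_DIR = WORLD_DIR / "stack"
TRUTH_DIR = WORLD_DIR / "truth"
MODELS_DIR = RESULTS / "models"
FIGURES_DIR = RESULTS / "figures"


def study_config() -> SimConfig:
    return SimConfig(seed=SEED)


def load_stack() -> VariableStack:
    manifest = json.loads((WORLD_DIR / "manifest.json").read_text())
    names = manifest["variables"]
    roles = manifest["roles"]
    layers = {n: read_raster(STACK_DIR / f"{n}.asc") for n in names}
    return VariableStack(names, layers, roles)
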