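"""Shared configuration for the numbered analysis drivers.

One full-size simulated study (20 participants, 680 trials each, all
artifact processes switched on) analysed end to end.  Permutation counts
are set to 2000 here to keep a desktop run inside a few minutes; raise
them (10,000 in the study configuration defaults) for publication-grade
Monte-Carlo error.
"""

import pickle
from pathlib import Path

from alphaphase.config import SimConfig, StudyConfig

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"

STUDY = StudyConfig(
    sim=SimConfig(seed=2016),
    n_perm_electrode=2000,
    n_perm_time=2000,
    n_perm_moore=2000,
    uniformity_reps=20_000,
    analysis_seed=12345,
)

FEATURES_PICKLE = SCRATCH / "features.pkl"


def save_features(feats):
    SCRATCH.mkdir(exist_ok=True)
    with open(FEATURES_PICKLE, "wb") as fh:
        pickle.dump(feats, fh, protocol=4)


def load_features():
    if not FEATURES_PICKLE.exists():
        raise SystemExit("run 01_simulate_and_screen.py first")
    with open(FEATURES_PICKLE, "rb") as fh:
        return pickle.load(fh)


def ensure_dirs():
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)
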