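"""Shared paths and loading for the numbered analysis drivers.

Every driver takes ``--seed`` (default 1) and writes its tables under
``results/``.  Driver 01 creates the panel; later drivers reload it from
disk so each step can be rerun independently.
"""

import argparse
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "src"))

RESULTS = ROOT / "results"
FIXTURE = RESULTS / "fixture"


def parse_seed(description):
    ap = argparse.ArgumentParser(description=description)
    ap.add_argument("--seed", type=int, default=1)
    return ap.parse_args().seed


def load_panel():
    from riqtl.simulate import load_fixture
    if not FIXTURE.exists():
        raise SystemExit("run analysis/01_simulate_panel.py first")
    return load_fixture(FIXTURE)
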