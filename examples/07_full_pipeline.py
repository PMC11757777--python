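"""Run the whole two-stage pipeline on synthetic data (a few minutes).

Generates a source domain, pretrains the segmenter, pseudo-labels a
colour-shifted target domain, fine-tunes, densifies labelled fields of
view, trains the three classifiers, and writes metrics plus an
entropy-TOPSIS ranking under ``artifacts/pipeline_demo``.  The YAML next to
this script raises the demo's epochs/learning rate so the tiny models
actually converge; rerunning with the same seed reproduces metrics.json
bit for bit.
"""

import json
from pathlib import Path

from oraltils.config import validate_config
from oraltils.pipeline import run_pipeline

cfg = validate_config(Path(__file__).with_name("pipeline_demo.yaml"))
artifacts = run_pipeline(cfg)
metrics = json.loads((artifacts / "metrics.json").read_text())
print(json.dumps(metrics, indent=2))
print(f"\nartifacts in {artifacts}")
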