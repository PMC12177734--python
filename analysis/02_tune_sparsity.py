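"""Choose the L1 sparsity level by permutation z-score on the training half.

For each grid value the total inner AVE of the fitted model is compared with
models refitted to participant-permuted views (100 permutations per step);
the lambda maximizing z is carried forward.

Run after 01:  python analysis/02_tune_sparsity.py
"""

import json
from pathlib import Path

import pandas as pd

from sgccapipe.config import validate_config
from sgccapipe.pipeline import run_pipeline

cfg = validate_config(Path(__file__).parent / "study_config.yaml")
run_pipeline(cfg, stages=("tune",))

out = Path(cfg.output_dir)
table = pd.read_csv(out / "tuning.tsv", sep="\t")
chosen = json.loads((out / "tuning.json").read_text())
print(table.round(4).to_string(index=False))
print(f"\nchosen lambda = {chosen['chosen_lambda']} (z = {chosen['z_at_chosen']:.1f})")
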