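"""Permutation significance of each component in training and held-out data.

200 randomized models are fitted to participant-permuted training views; the
observed inner AVE is ranked among them on the training half, and the test
half is projected through both the actual and the randomized models.

Run after 03:  python analysis/04_significance.py
"""

from pathlib import Path

import pandas as pd

from sgccapipe.config import validate_config
from sgccapipe.pipeline import run_pipeline

cfg = validate_config(Path(__file__).parent / "study_config.yaml")
run_pipeline(cfg, stages=("significance",))

table = pd.read_csv(Path(cfg.output_dir) / "significance.tsv", sep="\t")
print(table.round(4).to_string(index=False))
n_sig = int(((table["context"] == "test") & (table["p_perm"] < 0.05)).sum())
print(f"\ntest-significant components at alpha = 0.05: {n_sig}")
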