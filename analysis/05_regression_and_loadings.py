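"""Regress clinical scores on imaging scores; report structural coefficients.

For every component, the clinical component score is regressed on the seven
imaging component scores (1000 bootstrap resamples, bias-corrected CIs,
coefficient flags at P < .008); each component score is then correlated back
to its view's variables, with BH-FDR within each component x view family,
and clinical coefficients are aggregated into section means.

Run after 04:  python analysis/05_regression_and_loadings.py
"""

import json
from pathlib import Path

import pandas as pd

from sgccapipe.config import validate_config
from sgccapipe.pipeline import run_pipeline

cfg = validate_config(Path(__file__).parent / "study_config.yaml")
run_pipeline(cfg, stages=("regression", "loadings", "report"))

out = Path(cfg.output_dir)
fits = pd.read_csv(out / "regression_fit.tsv", sep="\t")
print("clinical ~ imaging score regressions:")
print(fits.round(3).to_string(index=False))

sig = pd.read_csv(out / "structural_coefficients.tsv", sep="\t")
n_sig = int(sig["significant"].sum())
print(f"\nsignificant structural coefficients (FDR < .05): {n_sig} of {len(sig)}")

agg = pd.read_csv(out / "aggregated_loadings.tsv", sep="\t").dropna()
if len(agg):
    lead = agg.loc[agg.groupby("component")["aggregated_loading"]
                   .apply(lambda s: s.abs().idxmax())]
    print("\nleading clinical section per component (aggregated loading):")
    print(lead.round(3).to_string(index=False))

report = json.loads((out / "report.json").read_text())
print(f"\nreport.json: {report['n_test_significant_components']} "
      "test-significant component(s)")
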