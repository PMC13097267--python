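"""Full cohort analysis: simulate, run the pipeline, evaluate response markers.

Generates a 15+15 synthetic cohort, runs every stage (cohort thresholds,
habitat maps, longitudinal features), then compares groups and evaluates
the two candidate treatment-response markers — the change in myosteatosis
volume (dvol_LH) and the relative change in whole-muscle volume
(dpct_volume_whole) — singly and combined by logistic regression.
"""

import json
import tempfile
from pathlib import Path

import pandas as pd

from eomhabitat import PhantomSpec, RunConfig, generate_cohort, run_all
from eomhabitat.stats import compare_feature

with tempfile.TemporaryDirectory() as tmp:
    manifest = generate_cohort(15, 15, Path(tmp) / "cohort", PhantomSpec(), jitter=0.15, seed=3)
    run_dir = run_all(manifest, Path(tmp) / "run", RunConfig(write_labelmaps=False))
    thresholds = json.loads((run_dir / "thresholds.json").read_text())
    features = pd.read_csv(run_dir / "features.csv")
    roc = pd.read_csv(run_dir / "roc_report.csv")

print(f"cohort thresholds: water {thresholds['t_water']:.1f}, fat {thresholds['t_fat']:.1f}")
for feat in ("dvol_LH", "dpct_volume_whole"):
    res = compare_feature(features, feat)
    print(f"{feat}: {res.test_used} p = {res.p_value:.2g}")
print()
print(roc[["parameter", "cutoff", "auc", "sensitivity_pct", "specificity_pct"]].to_string(index=False))
# Responders gain myosteatosis volume and lose whole-muscle volume, so both
# markers discriminate; the combined logistic score should have an AUC at
# least as high as either marker alone (in-sample).
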