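"""Rank features and cross-validate the classifier grid.

Runs the four rankers x four classifiers on the low-vs-high task under
patient-grouped 3-fold CV, reports per-cell AUC and per-patient voting
accuracy, and writes the grid to results/cv_grid.csv plus the top-ranked
features to results/top_features.json.
"""

import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from nucmorph.pipeline import ExperimentConfig, run_experiment

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"

sys.path.insert(0, str(ROOT / "analysis"))
from importlib import import_module

load_cases = import_module("02_extract_features").load_cases


def main():
    cases = load_cases()
    table = pd.read_csv(ROOT / "scratch" / "features" / "features_separated.csv")
    config = ExperimentConfig(tasks=("LvsH",), n_iterations=3, seed=1)
    report = run_experiment(cases, table, config)
    RESULTS.mkdir(exist_ok=True)
    rows = list(report["cells"].values())
    grid = pd.DataFrame(rows).drop(columns=["top_features"])
    grid.to_csv(RESULTS / "cv_grid.csv", index=False)
    tops = {k: v["top_features"] for k, v in report["cells"].items()}
    (RESULTS / "top_features.json").write_text(json.dumps(tops, indent=2))
    best = grid.sort_values("auc_mean", ascending=False).iloc[0]
    print(grid.to_string(index=False))
    print(
        f"\nbest cell: {best.ranker} + {best.classifier} "
        f"(AUC {best.auc_mean:.3f}, voting accuracy {best.voting_accuracy_mean:.3f})"
    )


if __name__ == "__main__":
    main()
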