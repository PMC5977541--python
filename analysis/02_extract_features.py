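"""Extract the 432-feature (and pooled 216-feature) tables for the cohort.

Reads the simulated patches from scratch/cohort/, computes the full
per-patch histomorphometric feature vectors in both compartment modes,
and writes the tables to scratch/features/.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from nucmorph.io import read_nuclei
from nucmorph.pipeline import extract_feature_table
from nucmorph.types import PatientCase
from nucmorph.pipeline import categorize_mbr, categorize_odx

ROOT = Path(__file__).resolve().parents[1]
COHORT = ROOT / "scratch" / "cohort"
OUT = ROOT / "scratch" / "features"


def load_cases():
    manifest = pd.read_csv(COHORT / "manifest.csv")
    cases = {}
    for row in manifest.itertuples():
        if row.patient_id not in cases:
            cases[row.patient_id] = PatientCase(
                patient_id=row.patient_id,
                odx_score=int(row.odx_score),
                odx_category=categorize_odx(int(row.odx_score)),
                mbr_score=int(row.mbr_score),
                mbr_category=categorize_mbr(int(row.mbr_score)),
            )
        cases[row.patient_id].patches.append(read_nuclei(row.patch_path))
    return list(cases.values())


def main():
    cases = load_cases()
    OUT.mkdir(parents=True, exist_ok=True)
    for mode in ("separated", "pooled"):
        table = extract_feature_table(cases, mode=mode)
        table.to_csv(OUT / f"features_{mode}.csv", index=False)
        print(
            f"{mode}: {table.shape[0]} patches x {table.shape[1] - 3} features, "
            f"{int(table.excluded.sum())} excluded"
        )


if __name__ == "__main__":
    main()
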