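#!/usr/bin/env python
"""Univariable robust regressions of district flu mortality on each
ecological determinant, for the first (1889/90) and recurrence
(1893/94) seasons.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from fluexcess import datamodel as dm
from fluexcess.regression import results_to_frame, run_determinant_panel

BASE = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    path = BASE / "data" / "districts.csv"
    if not path.exists():
        raise SystemExit("run 01_simulate_data.py first")
    records = dm.read_district_table(path)
    fits = []
    for year in ("1889/90", "1893/94"):
        fits.extend(run_determinant_panel(records, outcome_year=year))
    frame = results_to_frame(fits)
    frame.to_csv(BASE / "determinants.csv", index=False)
    print("robust slopes (deaths per 1000 per unit of determinant):")
    for r in fits:
        mark = "*" if r.significant else " "
        print(f"  {r.outcome_label}  {r.predictor_label:24s} "
              f"{r.slope:+10.4f} [{r.ci_low:+10.4f}, {r.ci_high:+10.4f}]{mark}")
    print(f"-> {BASE / 'determinants.csv'}")


if __name__ == "__main__":
    main()
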