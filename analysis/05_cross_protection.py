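#!/usr/bin/env python
"""Cross-protection between the first wave and the 1893/94 recurrence.

Robust slope of 1893/94 district flu mortality on (a) 1889/90
mortality, (b) cumulative 1889-1893 mortality, (c) the physicians'
1890 attack-rate estimate, with urban/rural OLS lines. A significantly
positive slope speaks against cross-protection.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from fluexcess import datamodel as dm
from fluexcess.regression import cross_protection, results_to_frame

BASE = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    path = BASE / "data" / "districts.csv"
    if not path.exists():
        raise SystemExit("run 01_simulate_data.py first")
    records = dm.read_district_table(path)
    fits = []
    for earlier in ("1889/90", "cumulative", "attack_rate_1890"):
        fit, lines = cross_protection(records, earlier=earlier)
        fits.append(fit)
        verdict = ("speaks against cross-protection" if fit.ci_low > 0 else
                   "consistent with cross-protection" if fit.ci_high < 0 else
                   "no clear association")
        print(f"  later ~ {earlier:16s}: slope {fit.slope:+.3f} "
              f"[{fit.ci_low:+.3f}, {fit.ci_high:+.3f}] -> {verdict}")
        for label, line in lines.items():
            print(f"      {label:5s} OLS line: slope {line['slope']:+.3f} "
                  f"(n={line['n']})")
    results_to_frame(fits).to_csv(BASE / "cross_protection.csv", index=False)
    print(f"-> {BASE / 'cross_protection.csv'}")


if __name__ == "__main__":
    main()
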