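#!/usr/bin/env python
"""Generate the synthetic surveillance tables every later step consumes.

Writes monthly_deaths.csv (three city-like units, ten years, a x1.589
mortality shock in January 1890), districts.csv (182 districts on a
13x14 lattice with a central hotspot and signed covariate effects) and
adjacency.csv into results/data/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from fluexcess import datamodel as dm
from fluexcess.synthetic import (
    DEFAULT_SEED,
    DistrictScenario,
    SeriesScenario,
    simulate_district_table,
    simulate_monthly_series,
)

OUT = Path(__file__).resolve().parents[1] / "results" / "data"


def main(seed: int = DEFAULT_SEED) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    series = [
        simulate_monthly_series(SeriesScenario(seed=seed + k,
                                               unit_id=f"unit{k + 1}"))
        for k in range(3)
    ]
    dm.write_monthly_series(series, OUT / "monthly_deaths.csv")
    records, weights = simulate_district_table(DistrictScenario(seed=seed))
    dm.write_district_table(records, OUT / "districts.csv")
    edges = sorted({tuple(sorted((a, b)))
                    for a, ns in weights.neighbours.items() for b in ns})
    dm.write_adjacency_csv(edges, OUT / "adjacency.csv")
    total = sum(int(s.deaths.sum()) for s in series)
    print(f"wrote {len(series)} monthly series ({total} deaths total), "
          f"{len(records)} districts, {len(edges)} adjacency edges -> {OUT}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else DEFAULT_SEED)
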