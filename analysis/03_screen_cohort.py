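#!/usr/bin/env python
"""Screen the cohort for active disease and multi-analyte outliers.

Health screening removes animals with active lesions from the
reference-interval dataset; the cross-analyte screen (per-analyte Horn
flags within season, animals flagged on ≥2 analytes) removes suspected
pathologic animals from both modelling and reference intervals.  Checks
the excluded set against the simulator's injection log.

Inputs: results/cohort.csv, results/corrected.csv, results/injection_log.json
Output: results/exclusions.csv
"""

import json
from pathlib import Path

import pandas as pd

from ectogas.core import (
    cohort_to_frame,
    read_cohort,
    screen_health,
    screen_multi_analyte_outliers,
    write_table,
)
from ectogas.pipeline import _season_horn_flags

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    observations = read_cohort(OUT / "cohort.csv").observations
    corrected = pd.read_csv(OUT / "corrected.csv")

    health = {r.id: r for r in (screen_health(o) for o in observations)}
    outlier = {
        r.id: r for r in screen_multi_analyte_outliers(_season_horn_flags(corrected))
    }
    rows = []
    for o in observations:
        h, m = health[o.id], outlier.get(o.id)
        rows.append(
            {
                "id": o.id,
                "eligible_ri": h.eligible_ri and (m is None or m.eligible_ri),
                "eligible_model": m is None or m.eligible_model,
                "reasons": ";".join(h.reasons + (m.reasons if m else ())),
            }
        )
    table = pd.DataFrame(rows)
    write_table(table, OUT / "exclusions.csv")

    excluded = set(table.loc[~table["eligible_model"], "id"])
    injected = {
        e["id"] for e in json.loads((OUT / "injection_log.json").read_text())["outliers"]
    }
    print(f"screened {len(table)} animals")
    print(f"excluded from modelling/RIs (>=2 outlier analytes): {sorted(excluded)}")
    print(f"injected pathologic animals: {sorted(injected)}; "
          f"caught: {len(injected & excluded)}/{len(injected)}")


if __name__ == "__main__":
    main()
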