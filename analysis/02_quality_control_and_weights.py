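#!/usr/bin/env python
"""Apply the protocol-compliance exclusions and rake the sample to
general-population margins.

Removes feedback-flagged cTTO rows, respondents spending under five minutes
on the ten cTTO tasks, and respondents whose 55555 valuation is inconsistent
with their other responses; then computes raking weights matching the sample
to the population margins for age, sex, education and region.  Writes the
cleaned tables, the QC report and per-respondent weights.
"""

import json
from pathlib import Path

import pandas as pd

from eqvalue import NORWAY_POPULATION_MARGINS, compute_weights, qc_exclude
from eqvalue.io import read_interview_data, write_interview_data

RESULTS = Path("results/analysis")


def main() -> None:
    data = RESULTS / "data"
    dataset = read_interview_data(
        data / "ctto.csv", data / "dce.csv", data / "respondents.csv"
    )
    clean, report = qc_exclude(dataset)
    print("QC exclusions:")
    for key in (
        "n_flagged_rows_removed",
        "n_excluded_fast_interview",
        "n_excluded_worst_state_rule",
        "n_excluded_total",
    ):
        print(f"  {key}: {report[key]}")
    (RESULTS / "qc_report.json").write_text(json.dumps(report, indent=2, default=int))
    write_interview_data(clean, RESULTS / "clean")

    weights = compute_weights(clean.respondents, NORWAY_POPULATION_MARGINS)
    out = pd.DataFrame({"id": clean.respondents["id"], "weight": weights.to_numpy()})
    out.to_csv(RESULTS / "weights.csv", index=False)
    print(
        f"raked weights for {len(out)} respondents: "
        f"min {out.weight.min():.3f}, max {out.weight.max():.3f}"
    )


if __name__ == "__main__":
    main()
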