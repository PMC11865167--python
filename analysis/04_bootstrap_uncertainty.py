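#!/usr/bin/env python
"""Bootstrap the selected model at the respondent level.

Respondents are resampled with replacement (cTTO and DCE records travel
together), raking weights are re-derived inside every replicate, and the
hybrid model is refitted from the full-data optimum.  Writes coefficient SEs
and percentile 95% CIs, and the 3,125-state value set with per-state SEs and
CIs.  B defaults to 200 here; pass --B to change it.
"""

import argparse
from pathlib import Path

import pandas as pd

from eqvalue import (
    FitOptions,
    ModelSpec,
    NORWAY_POPULATION_MARGINS,
    bootstrap,
    compute_weights,
)
from eqvalue.io import read_interview_data

RESULTS = Path("results/analysis")


def weights_procedure(respondents):
    w = compute_weights(respondents, NORWAY_POPULATION_MARGINS)
    return pd.Series(w.to_numpy(), index=respondents["id"].to_numpy())


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--B", type=int, default=200)
    parser.add_argument("--seed", type=int, default=2)
    args = parser.parse_args()

    clean = RESULTS / "clean"
    dataset = read_interview_data(
        clean / "ctto.csv", clean / "dce.csv", clean / "respondents.csv"
    )
    label_path = RESULTS / "selected_model.txt"
    label = label_path.read_text().strip() if label_path.exists() else "hybrid_mult8"
    spec = ModelSpec(
        form="additive20" if "add20" in label else "multiplicative8",
        intercept="intercept" in label,
        data="ctto_only" if label.startswith("ctto") else "hybrid",
    )
    print(f"bootstrapping the selected model: {label}")
    result = bootstrap(
        spec,
        dataset,
        B=args.B,
        seed=args.seed,
        weights_procedure=weights_procedure,
        options=FitOptions(n_quad=15, n_starts=1),
    )
    result.coefficients.to_csv(RESULTS / "coefficients_ci.csv")
    result.values.to_csv(RESULTS / "value_set.csv")
    print(f"bootstrap: {result.n_converged}/{result.n_requested} replicates converged")
    print(result.coefficients.round(4).to_string())


if __name__ == "__main__":
    main()
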