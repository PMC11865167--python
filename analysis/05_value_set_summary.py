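#!/usr/bin/env python
"""Summarise the estimated value set and plot its distribution.

Reports the value range, the share of states worse than dead, the gap between
full health and the next-best state, single-level transition statistics, and
the dimension ranking, alongside the same statistics for the published
coefficient table.  Saves a histogram of the 3,125 predicted values.
"""

import json
from pathlib import Path

from eqvalue import NORWAY_COEFFICIENTS, score_all_states, valueset_summary
from eqvalue.state_space import read_coefficients

RESULTS = Path("results/analysis")


def main() -> None:
    fitted = read_coefficients(RESULTS / "selected_coefficients.csv")
    rows = {}
    for label, coeffs in (("fitted", fitted), ("published", NORWAY_COEFFICIENTS)):
        vs = score_all_states(coeffs)
        s = valueset_summary(vs)
        rows[label] = s
        print(f"{label}:")
        for key in (
            "min",
            "n_worse_than_dead",
            "pct_worse_than_dead",
            "best_next_gap",
            "mean_single_level_transition",
            "sd_single_level_transition",
        ):
            print(f"  {key}: {s[key]:.4f}" if isinstance(s[key], float) else f"  {key}: {s[key]}")
        print(f"  dimension_ranking: {' '.join(s['dimension_ranking'])}")
    (RESULTS / "value_set_summary.json").write_text(json.dumps(rows, indent=2))

    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(7, 4))
        ax.hist(score_all_states(fitted).utilities, bins=60, alpha=0.6, label="fitted")
        ax.hist(
            score_all_states(NORWAY_COEFFICIENTS).utilities,
            bins=60,
            histtype="step",
            label="published",
        )
        ax.set_xlabel("predicted utility")
        ax.set_ylabel("number of health states")
        ax.legend()
        fig.tight_layout()
        fig.savefig(RESULTS / "value_distribution.png", dpi=120)
        print(f"wrote {RESULTS / 'value_distribution.png'}")
    except ImportError:
        print("matplotlib unavailable; skipped the distribution plot")


if __name__ == "__main__":
    main()
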