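"""Simulated EQ-VT valuation interviews with the statistical structure the
models assume.

The generator draws, for respondent *i* valuing state *s*:

    du*_is = v_s + a_i + eps_is,   a_i ~ N(0, tau^2),  eps_is ~ N(0, sigma_s^2)

with heteroscedastic noise linear in the state's true disutility,
``sigma_s = sigma_a + sigma_b * v_s``.  The latent disutility is
right-censored at 2 (the cTTO response floor of -1); the observed cTTO value
is ``1 - min(du*, 2)``, clamped to [-1, 1] and rounded to the task's 0.05
response grid.  DCE choices follow a conditional logit on the same
disutilities with scale parameter theta:
``P(choose A) = logistic(theta * (du_B - du_A))``.

``simulate_study`` assembles a full interview dataset: respondents randomized
to cTTO/DCE blocks, demographics drawn from supplied margins, interview
durations, and (optionally) injected protocol violations for exercising the
quality-control rules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .designs import CTTODesign, DCEDesign, generate_ctto_design, generate_dce_design
from .state_space import NORWAY_COEFFICIENTS, CoefficientSet

__all__ = [
    "TruePreferences",
    "InterviewDataset",
    "DEFAULT_TRUTH",
    "NORWAY_POPULATION_MARGINS",
    "simulate_ctto",
    "simulate_dce",
    "simulate_study",
]

RESPONSE_GRID = 0.05

#: General-population margins used as simulation defaults (Norwegian adult
#: population, Statistics Norway, October 1 2022).
NORWAY_POPULATION_MARGINS: dict[str, dict[str, float]] = {
    "sex": {"female": 0.498, "male": 0.502},
    "age_group": {"18-34": 0.285, "35-66": 0.518, "67+": 0.197},
    "education": {
        "below_upper_secondary": 0.200,
        "upper_secondary": 0.421,
        "higher_lt4": 0.260,
        "higher_ge4": 0.119,
    },
    "region": {"east": 0.376, "mid": 0.137, "north": 0.092, "south": 0.190, "west": 0.205},
}


@dataclass
class TruePreferences:
    """Data-generating parameters for a simulated valuation study.

    tau is the respondent random-intercept SD on the disutility scale;
    sigma_a / sigma_b give the residual SD ``sigma_s = sigma_a + sigma_b*v_s``;
    theta is the DCE logit scale.
    """

    coeffs: CoefficientSet
    tau: float = 0.15
    sigma_a: float = 0.25
    sigma_b: float = 0.10
    theta: float = 3.0

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        if self.theta <= 0:
            raise ValueError("theta must be > 0")

    def sigma_of(self, v: np.ndarray) -> np.ndarray:
        return self.sigma_a + self.sigma_b * v


#: Standard synthetic truth for tests: the published Norwegian structural
#: coefficients with documented nuisance values (the study does not print
#: fitted tau, sigma_a, sigma_b, theta).
DEFAULT_TRUTH = TruePreferences(coeffs=NORWAY_COEFFICIENTS)


@dataclass
class InterviewDataset:
    """Respondent-level interview data.

    ctto: respondent_id, block, state_code, value, flagged, duration_min
    dce: respondent_id, block, state_a, state_b, chose_a
    respondents: id, ctto_block, dce_block, age_group, sex, education, region,
    duration_min [, weight]
    """

    ctto: pd.DataFrame
    dce: pd.DataFrame
    respondents: pd.DataFrame

    def subset(self, respondent_ids) -> "InterviewDataset":
        ids = set(respondent_ids)
        return InterviewDataset(
            ctto=self.ctto[self.ctto["respondent_id"].isin(ids)].reset_index(drop=True),
            dce=self.dce[self.dce["respondent_id"].isin(ids)].reset_index(drop=True),
            respondents=self.respondents[self.respondents["id"].isin(ids)].reset_index(drop=True),
        )


def _state_disutilities(coeffs: CoefficientSet, codes: list[str]) -> np.ndarray:
    levels = np.array([[int(c) for c in code] for code in codes])
    return coeffs.disutility_of_levels(levels)


def round_to_grid(values: np.ndarray) -> np.ndarray:
    """Snap to the 0.05 cTTO response grid within [-1, 1]."""
    return np.clip(np.round(np.asarray(values) / RESPONSE_GRID) * RESPONSE_GRID, -1.0, 1.0)


def simulate_ctto(
    truth: TruePreferences,
    design: CTTODesign,
    n_respondents: int,
    seed: int,
    block_assignment: np.ndarray | None = None,
    respondent_ids: np.ndarray | None = None,
) -> pd.DataFrame:
    """Simulate cTTO valuations; one row per (respondent, design state)."""
    rng = np.random.default_rng(seed)
    if block_assignment is None:
        block_assignment = rng.integers(0, len(design.blocks), size=n_respondents)
    if respondent_ids is None:
        respondent_ids = np.arange(n_respondents)
    universe = design.universe
    v_universe = _state_disutilities(truth.coeffs, universe)
    sigma = truth.sigma_of(v_universe)
    if np.any(sigma <= 0):
        bad = [universe[i] for i in np.where(sigma <= 0)[0]]
        raise ValueError(f"sigma_s <= 0 for design states {bad[:5]}")
    v_of = dict(zip(universe, v_universe))
    s_of = dict(zip(universe, sigma))

    a = rng.normal(0.0, truth.tau, size=n_respondents)
    rows = []
    for r in range(n_respondents):
        states = design.states_in_block(int(block_assignment[r]))
        v = np.array([v_of[s] for s in states])
        sig = np.array([s_of[s] for s in states])
        du_star = v + a[r] + rng.normal(0.0, 1.0, size=len(states)) * sig
        value = round_to_grid(1.0 - np.minimum(du_star, 2.0))
        for s, val in zip(states, value):
            rows.append((int(respondent_ids[r]), int(block_assignment[r]), s, float(val)))
    df = pd.DataFrame(rows, columns=["respondent_id", "block", "state_code", "value"])
    df["flagged"] = False
    return df


def simulate_dce(
    truth: TruePreferences,
    design: DCEDesign,
    n_respondents: int,
    seed: int,
    block_assignment: np.ndarray | None = None,
    respondent_ids: np.ndarray | None = None,
) -> pd.DataFrame:
    """Simulate DCE choices; one row per (respondent, design pair)."""
    rng = np.random.default_rng(seed)
    if block_assignment is None:
        block_assignment = rng.integers(0, len(design.blocks), size=n_respondents)
    if respondent_ids is None:
        respondent_ids = np.arange(n_respondents)
    all_codes = sorted({c for block in design.blocks for pair in block for c in pair})
    v_of = dict(zip(all_codes, _state_disutilities(truth.coeffs, all_codes)))
    rows = []
    for r in range(n_respondents):
        pairs = design.blocks[int(block_assignment[r])]
        for a_code, b_code in pairs:
            p_a = 1.0 / (1.0 + np.exp(-truth.theta * (v_of[b_code] - v_of[a_code])))
            chose_a = bool(rng.random() < p_a)
            rows.append(
                (int(respondent_ids[r]), int(block_assignment[r]), a_code, b_code, chose_a)
            )
    return pd.DataFrame(rows, columns=["respondent_id", "block", "state_a", "state_b", "chose_a"])


def _draw_demographics(
    rng: np.random.Generator, n: int, margins: dict[str, dict[str, float]]
) -> pd.DataFrame:
    cols = {}
    for char, cats in margins.items():
        labels = list(cats)
        p = np.array([cats[c] for c in labels], dtype=float)
        p = p / p.sum()
        cols[char] = rng.choice(labels, size=n, p=p)
    return pd.DataFrame(cols)


def simulate_study(
    truth: TruePreferences = DEFAULT_TRUTH,
    n_respondents: int = 1237,
    seed: int = 0,
    demographics_margins: dict[str, dict[str, float]] | None = None,
    ctto_design: CTTODesign | None = None,
    dce_design: DCEDesign | None = None,
    fast_interview_rate: float = 0.0,
    misvalued_worst_rate: float = 0.0,
    feedback_flag_rate: float = 0.0,
) -> InterviewDataset:
    """Simulate a complete valuation study.

    Each respondent values the 10 cTTO states of their block and answers the
    7 DCE pairs of their block.  Interview durations are drawn lognormal
    (median ~16 min for the ten cTTO tasks); optional protocol violations are
    injected for QC testing: "fast" interviews get a duration below 5 minutes,
    "misvalued worst" respondents have their 55555 value raised above their
    other valuations, and feedback flags mark individual cTTO rows for
    removal.
    """
    rng = np.random.default_rng(seed)
    margins = demographics_margins or NORWAY_POPULATION_MARGINS
    if ctto_design is None:
        ctto_design = generate_ctto_design(int(rng.integers(2**31)))
    if dce_design is None:
        dce_design = generate_dce_design(int(rng.integers(2**31)))

    ids = np.arange(n_respondents)
    ctto_blocks = rng.integers(0, len(ctto_design.blocks), size=n_respondents)
    dce_blocks = rng.integers(0, len(dce_design.blocks), size=n_respondents)
    demo = _draw_demographics(rng, n_respondents, margins)
    duration = np.exp(rng.normal(np.log(16.0), 0.35, size=n_respondents))
    duration = np.maximum(duration, 5.5)

    fast = rng.random(n_respondents) < fast_interview_rate
    duration[fast] = rng.uniform(2.0, 4.9, size=int(fast.sum()))

    respondents = pd.DataFrame(
        {
            "id": ids,
            "ctto_block": ctto_blocks,
            "dce_block": dce_blocks,
            "duration_min": duration,
        }
    ).join(demo)

    ctto = simulate_ctto(
        truth,
        ctto_design,
        n_respondents,
        seed=int(rng.integers(2**31)),
        block_assignment=ctto_blocks,
        respondent_ids=ids,
    )
    dce = simulate_dce(
        truth,
        dce_design,
        n_respondents,
        seed=int(rng.integers(2**31)),
        block_assignment=dce_blocks,
        respondent_ids=ids,
    )

    # inject 55555 misvaluations: worst state valued >= 0.5 above the minimum
    misvalued = ids[rng.random(n_respondents) < misvalued_worst_rate]
    for rid in misvalued:
        mask = ctto["respondent_id"] == rid
        others = ctto.loc[mask & (ctto["state_code"] != "55555"), "value"]
        target = round_to_grid(np.array([others.min() + 0.6]))[0]
        ctto.loc[mask & (ctto["state_code"] == "55555"), "value"] = target

    if feedback_flag_rate > 0:
        ctto["flagged"] = rng.random(len(ctto)) < feedback_flag_rate

    ctto = ctto.merge(
        respondents[["id", "duration_min"]].rename(columns={"id": "respondent_id"}),
        on="respondent_id",
    )
    return InterviewDataset(ctto=ctto, dce=dce, respondents=respondents)
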