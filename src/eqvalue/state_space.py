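"""EQ-5D-5L health states, scoring under a coefficient set, and value-set summaries.

An EQ-5D-5L health state is a five-digit code giving the level (1 = no problems
.. 5 = extreme problems) on each of five dimensions: mobility (MO), self-care
(SC), usual activities (UA), pain/discomfort (PD) and anxiety/depression (AD).
There are 5**5 = 3,125 distinct states.  A value set maps every state to a
societal utility anchored at 1 (full health, state 11111) and 0 (dead);
negative utilities mean "worse than dead".

Two structural forms are supported for the disutility ``du(s) = 1 - u(s)``:

* ``additive20`` — one coefficient per dimension-level dummy,
  ``du = alpha + sum_{d,l>=2} beta_{d,l} x_{d,l}``;
* ``multiplicative8`` — a dimension weight times a shared level multiplier,
  ``du = alpha + sum_d beta_d * L_{l(d)}`` with the convention
  ``L_1 = 0, L_5 = 1`` so that 8 structural parameters remain free
  (five beta_d plus L_2, L_3, L_4).

The intercept ``alpha``, when present, applies to every state except 11111.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DIMENSIONS",
    "HealthState",
    "CoefficientSet",
    "ValueSet",
    "NORWAY_COEFFICIENTS",
    "disutility",
    "score_state",
    "enumerate_states",
    "score_all_states",
    "valueset_summary",
    "is_consistent",
    "read_value_set",
    "write_value_set",
    "read_coefficients",
    "write_coefficients",
]

DIMENSIONS: tuple[str, ...] = ("MO", "SC", "UA", "PD", "AD")


@dataclass(frozen=True, order=True)
class HealthState:
    """A five-digit EQ-5D-5L profile, e.g. ``HealthState.from_code("15432")``."""

    levels: tuple[int, int, int, int, int]

    def __post_init__(self) -> None:
        if len(self.levels) != 5 or any(l not in (1, 2, 3, 4, 5) for l in self.levels):
            raise ValueError(f"invalid EQ-5D-5L levels: {self.levels!r}")

    @classmethod
    def from_code(cls, code: str | int) -> "HealthState":
        code = str(code)
        if len(code) != 5 or not code.isdigit():
            raise ValueError(f"invalid EQ-5D-5L state code: {code!r}")
        return cls(tuple(int(c) for c in code))  # type: ignore[arg-type]

    @property
    def code(self) -> str:
        return "".join(str(l) for l in self.levels)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.code


def enumerate_states() -> list[HealthState]:
    """All 3,125 states in lexicographic code order (11111 first, 55555 last)."""
    return [HealthState(levels) for levels in itertools.product((1, 2, 3, 4, 5), repeat=5)]


def _levels_matrix() -> np.ndarray:
    """(3125, 5) int array of levels, rows in lexicographic code order."""
    return np.array([s.levels for s in enumerate_states()], dtype=np.int64)


@dataclass
class CoefficientSet:
    """Structural coefficients of a value-set model.

    Parameters
    ----------
    form
        ``"multiplicative8"`` or ``"additive20"``.
    beta
        For multiplicative8: mapping dimension -> beta_d.
        For additive20: mapping ``f"{dim}{level}"`` (levels 2..5) -> beta_{d,l}.
    levels
        Multiplicative8 only: mapping {2: L2, 3: L3, 4: L4}.  L1 = 0 and
        L5 = 1 by convention.
    intercept
        Optional alpha, added to the disutility of every state except 11111.
    """

    form: str
    beta: Mapping[str, float]
    levels: Mapping[int, float] | None = None
    intercept: float | None = None

    def __post_init__(self) -> None:
        if self.form == "multiplicative8":
            missing = [d for d in DIMENSIONS if d not in self.beta]
            if missing:
                raise ValueError(f"missing dimension coefficients: {missing}")
            if self.levels is None or any(l not in self.levels for l in (2, 3, 4)):
                raise ValueError("multiplicative8 requires level multipliers L2, L3, L4")
        elif self.form == "additive20":
            missing = [
                f"{d}{l}" for d in DIMENSIONS for l in (2, 3, 4, 5) if f"{d}{l}" not in self.beta
            ]
            if missing:
                raise ValueError(f"missing dummy coefficients: {missing}")
        else:
            raise ValueError(f"unknown coefficient form: {self.form!r}")

    # -- scoring ------------------------------------------------------------

    def level_multipliers(self) -> np.ndarray:
        """[L1..L5] = [0, L2, L3, L4, 1] (multiplicative8 only)."""
        if self.form != "multiplicative8":
            raise ValueError("level multipliers are defined for multiplicative8 only")
        assert self.levels is not None
        return np.array([0.0, self.levels[2], self.levels[3], self.levels[4], 1.0])

    def dummy_matrix(self) -> np.ndarray:
        """(5, 5) array b[d, l-1] of per-dimension, per-level disutility increments.

        Row d, column l-1 holds the contribution of dimension d at level l
        (zero at level 1), valid for both forms.
        """
        b = np.zeros((5, 5))
        if self.form == "multiplicative8":
            L = self.level_multipliers()
            for i, d in enumerate(DIMENSIONS):
                b[i] = self.beta[d] * L
        else:
            for i, d in enumerate(DIMENSIONS):
                for l in (2, 3, 4, 5):
                    b[i, l - 1] = self.beta[f"{d}{l}"]
        return b

    def to_additive(self) -> "CoefficientSet":
        """Expand a multiplicative8 set to the equivalent additive20 set."""
        b = self.dummy_matrix()
        beta = {
            f"{d}{l}": float(b[i, l - 1]) for i, d in enumerate(DIMENSIONS) for l in (2, 3, 4, 5)
        }
        return CoefficientSet(form="additive20", beta=beta, intercept=self.intercept)

    def disutility_of_levels(self, levels: np.ndarray) -> np.ndarray:
        """Vectorised disutility for an (n, 5) integer level array."""
        b = self.dummy_matrix()
        du = np.zeros(len(levels))
        for i in range(5):
            du += b[i, levels[:, i] - 1]
        if self.intercept is not None:
            du += self.intercept * (levels != 1).any(axis=1)
        return du


#: Published Norwegian EQ-5D-5L value-set coefficients (hybrid multiplicative
#: 8-parameter model, no intercept), as printed to 3 decimal places.
NORWAY_COEFFICIENTS = CoefficientSet(
    form="multiplicative8",
    beta={"MO": 0.205, "SC": 0.206, "UA": 0.179, "PD": 0.391, "AD": 0.472},
    levels={2: 0.152, 3: 0.317, 4: 0.775},
)


def disutility(coeffs: CoefficientSet, state: HealthState | str) -> float:
    """Disutility ``du(s) = 1 - u(s)`` of a single state under ``coeffs``."""
    if isinstance(state, str):
        state = HealthState.from_code(state)
    levels = np.array([state.levels])
    return float(coeffs.disutility_of_levels(levels)[0])


def score_state(coeffs: CoefficientSet, state: HealthState | str) -> float:
    """Utility ``u(s) = 1 - du(s)``."""
    return 1.0 - disutility(coeffs, state)


@dataclass
class ValueSet:
    """Predicted utilities for all 3,125 states, optionally with SEs and CIs.

    ``table`` has index ``state_code`` (lexicographic) and columns
    ``utility`` [, ``se``, ``ci_low``, ``ci_high``].  ``provenance`` records
    how the values were produced (model spec, weighting flag, seeds ...).
    """

    table: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if "utility" not in self.table.columns:
            raise ValueError("value-set table requires a 'utility' column")
        codes = [s.code for s in enumerate_states()]
        if len(self.table) != 3125 or set(self.table.index) != set(codes):
            raise ValueError("value set must cover all 3,125 state codes exactly once")
        self.table = self.table.loc[codes]

    @property
    def utilities(self) -> np.ndarray:
        return self.table["utility"].to_numpy()

    def utility(self, state: HealthState | str) -> float:
        code = state.code if isinstance(state, HealthState) else str(state)
        return float(self.table.at[code, "utility"])


def score_all_states(coeffs: CoefficientSet, provenance: dict | None = None) -> ValueSet:
    """Score every state; returned in lexicographic order."""
    levels = _levels_matrix()
    u = 1.0 - coeffs.disutility_of_levels(levels)
    codes = ["".join(map(str, row)) for row in levels]
    table = pd.DataFrame({"utility": u}, index=pd.Index(codes, name="state_code"))
    return ValueSet(table, provenance=dict(provenance or {}, form=coeffs.form))


# -- summaries ---------------------------------------------------------------


def _single_level_transitions(values: np.ndarray) -> np.ndarray:
    """Utility drops for all single-level worsening moves l -> l+1.

    For every state and every dimension not already at level 5 there is one
    available move; 5 * 4 * 5**4 = 12,500 moves in total.
    """
    levels = _levels_matrix()
    code_index = {tuple(row): i for i, row in enumerate(levels)}
    drops = []
    for d in range(5):
        movable = levels[:, d] < 5
        src = levels[movable]
        dst = src.copy()
        dst[:, d] += 1
        i_src = np.fromiter((code_index[tuple(r)] for r in src), dtype=np.int64)
        i_dst = np.fromiter((code_index[tuple(r)] for r in dst), dtype=np.int64)
        drops.append(values[i_src] - values[i_dst])
    return np.concatenate(drops)


def valueset_summary(vs: ValueSet) -> dict:
    """Headline characteristics of a complete value set.

    Returns min/max, the count and percentage of states valued strictly worse
    than dead (u < 0), the gap between full health and the next-best state,
    the mean and SD of the utility drop over all 12,500 single-level worsening
    moves, and the dimension ranking.  The ranking orders dimensions by the
    disutility of having that single dimension at level 5 (for a
    multiplicative8 value set this equals ordering by beta_d), largest first.
    """
    u = vs.utilities
    codes = vs.table.index.to_numpy()
    n_wtd = int((u < 0).sum())
    not_best = codes != "11111"
    best_next_gap = float(vs.utility("11111") - u[not_best].max())
    drops = _single_level_transitions(u)
    # disutility of "only dimension d at level 5" states: 51111, 15111, ...
    solo = []
    for d in range(5):
        levels = [1, 1, 1, 1, 1]
        levels[d] = 5
        solo.append(1.0 - vs.utility("".join(map(str, levels))))
    order = np.argsort(solo)[::-1]
    return {
        "min": float(u.min()),
        "max": float(u.max()),
        "n_worse_than_dead": n_wtd,
        "pct_worse_than_dead": 100.0 * n_wtd / len(u),
        "best_next_gap": best_next_gap,
        "mean_single_level_transition": float(drops.mean()),
        "sd_single_level_transition": float(drops.std(ddof=0)),
        "dimension_ranking": [DIMENSIONS[i] for i in order],
        "transition_definition": "all 12,500 single-level worsening moves, move-weighted",
    }


# -- logical consistency -----------------------------------------------------


def _dominates(a: Sequence[int], b: Sequence[int]) -> bool:
    """True if state a weakly dominates b (no worse anywhere, better somewhere)."""
    return all(x <= y for x, y in zip(a, b)) and any(x < y for x, y in zip(a, b))


def is_consistent(obj: ValueSet | CoefficientSet) -> dict:
    """Check logical consistency: a dominated state never has the higher value.

    For a complete value set, consistency over all dominance pairs is
    equivalent to monotonicity over single-level worsening moves (any
    dominance relation decomposes into a chain of such moves), so only the
    12,500 moves are checked and reversals are reported as (better_code,
    worse_code) pairs.  For a multiplicative8 coefficient set without a
    negative intercept the shortcut "all beta_d > 0 and 0 < L2 < L3 < L4 < 1"
    is used.
    """
    if isinstance(obj, CoefficientSet):
        if obj.form == "multiplicative8" and (obj.intercept is None or obj.intercept >= 0):
            assert obj.levels is not None
            L = [obj.levels[2], obj.levels[3], obj.levels[4]]
            violations = []
            for d in DIMENSIONS:
                if not obj.beta[d] > 0:
                    violations.append(f"beta_{d} <= 0")
            if not (0 < L[0] < L[1] < L[2] < 1):
                violations.append("level multipliers not strictly increasing in (0, 1)")
            return {"consistent": not violations, "violations": violations}
        obj = score_all_states(obj)

    u = vs_u = obj.utilities
    levels = _levels_matrix()
    codes = obj.table.index.to_numpy()
    code_index = {tuple(row): i for i, row in enumerate(levels)}
    violations: list[tuple[str, str]] = []
    for d in range(5):
        movable = np.where(levels[:, d] < 5)[0]
        dst_levels = levels[movable].copy()
        dst_levels[:, d] += 1
        i_dst = np.fromiter((code_index[tuple(r)] for r in dst_levels), dtype=np.int64)
        bad = vs_u[movable] < u[i_dst]
        for i_s, i_t in zip(movable[bad], i_dst[bad]):
            violations.append((str(codes[i_s]), str(codes[i_t])))
    return {"consistent": not violations, "violations": violations}


# -- delimited-text interfaces ----------------------------------------------


def write_value_set(vs: ValueSet, path) -> None:
    vs.table.to_csv(path, index=True)


def read_value_set(path) -> ValueSet:
    table = pd.read_csv(path, dtype={"state_code": str}).set_index("state_code")
    return ValueSet(table)


_MULT8_PARAMS = ["MO", "SC", "UA", "PD", "AD", "L2", "L3", "L4"]


def write_coefficients(coeffs: CoefficientSet, path, se: Mapping[str, float] | None = None) -> None:
    """Write a coefficient table with columns parameter, estimate[, se]."""
    rows: list[dict] = []
    if coeffs.form == "multiplicative8":
        assert coeffs.levels is not None
        values = {d: coeffs.beta[d] for d in DIMENSIONS}
        values.update({f"L{l}": coeffs.levels[l] for l in (2, 3, 4)})
    else:
        values = {f"{d}{l}": coeffs.beta[f"{d}{l}"] for d in DIMENSIONS for l in (2, 3, 4, 5)}
    if coeffs.intercept is not None:
        values["INTERCEPT"] = coeffs.intercept
    for name, est in values.items():
        row = {"parameter": name, "estimate": est}
        if se is not None and name in se:
            row["se"] = se[name]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_coefficients(path) -> CoefficientSet:
    df = pd.read_csv(path)
    values = dict(zip(df["parameter"], df["estimate"]))
    intercept = values.pop("INTERCEPT", None)
    # nuisance parameters may ride along in fitted tables; they are not structural
    for extra in ("THETA", "SIGMA_A", "SIGMA_B", "SIGMA", "TAU"):
        values.pop(extra, None)
    if set(values) == set(_MULT8_PARAMS):
        return CoefficientSet(
            form="multiplicative8",
            beta={d: values[d] for d in DIMENSIONS},
            levels={l: values[f"L{l}"] for l in (2, 3, 4)},
            intercept=intercept,
        )
    expected = {f"{d}{l}" for d in DIMENSIONS for l in (2, 3, 4, 5)}
    if set(values) == expected:
        return CoefficientSet(form="additive20", beta=values, intercept=intercept)
    raise ValueError(f"unrecognised parameter names in {path}: {sorted(values)}")
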