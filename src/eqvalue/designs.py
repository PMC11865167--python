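"""cTTO and DCE experimental designs with the EQ-VT structural constraints.

The EQ-VT valuation protocol assigns each respondent one of 10 standardized
cTTO blocks of 10 health states — each block contains exactly one very mild
state (11112, 11121, 11211, 12111 or 21111), the worst state 55555, and 8
states of varying severity, with the blocks jointly covering 86 distinct
states — and one of 28 standardized DCE blocks of 7 state pairs.

The official EQ-VT design matrices are not public; this module provides a
validated loader for user-supplied designs plus a seeded generator producing
constraint-satisfying synthetic designs (severity-stratified, with every
dimension-level represented and an identifiable dummy design matrix).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .state_space import HealthState

__all__ = [
    "MILD_STATES",
    "WORST_STATE",
    "CTTODesign",
    "DCEDesign",
    "validate_design",
    "generate_ctto_design",
    "generate_dce_design",
    "read_ctto_design",
    "write_ctto_design",
    "read_dce_design",
    "write_dce_design",
]

MILD_STATES = ("11112", "11121", "11211", "12111", "21111")
WORST_STATE = "55555"


@dataclass
class CTTODesign:
    """10 blocks of 10 state codes each, jointly covering 86 distinct states."""

    blocks: list[list[str]]

    @property
    def universe(self) -> list[str]:
        """Sorted distinct states covered by the design."""
        return sorted({s for block in self.blocks for s in block})

    def states_in_block(self, block: int) -> list[str]:
        return list(self.blocks[block])


@dataclass
class DCEDesign:
    """28 blocks of 7 (state A, state B) pairs."""

    blocks: list[list[tuple[str, str]]]


def _check_codes(states, violations, where: str) -> None:
    for code in states:
        try:
            HealthState.from_code(code)
        except ValueError:
            violations.append(f"{where}: malformed state code {code!r}")


def validate_design(design: CTTODesign | DCEDesign) -> dict:
    """Check a design against the EQ-VT structural constraints.

    Returns ``{"valid": bool, "violations": [...]}`` with one message per
    violated constraint, naming the offending block.
    """
    violations: list[str] = []
    if isinstance(design, CTTODesign):
        if len(design.blocks) != 10:
            violations.append(f"10 blocks required, got {len(design.blocks)}")
        for i, block in enumerate(design.blocks):
            _check_codes(block, violations, f"block {i}")
            if len(block) != 10:
                violations.append(f"block {i}: 10 states required, got {len(block)}")
            if len(set(block)) != len(block):
                violations.append(f"block {i}: duplicate states")
            n_mild = sum(s in MILD_STATES for s in block)
            if n_mild != 1:
                violations.append(f"block {i}: exactly one very mild state required, got {n_mild}")
            if WORST_STATE not in block:
                violations.append(f"block {i}: missing worst state {WORST_STATE}")
        n_universe = len({s for b in design.blocks for s in b})
        if len(design.blocks) == 10 and n_universe != 86:
            violations.append(f"design must cover 86 distinct states, got {n_universe}")
    elif isinstance(design, DCEDesign):
        if len(design.blocks) != 28:
            violations.append(f"28 blocks required, got {len(design.blocks)}")
        for i, block in enumerate(design.blocks):
            if len(block) != 7:
                violations.append(f"block {i}: 7 pairs required, got {len(block)}")
            for a, b in block:
                _check_codes((a, b), violations, f"block {i}")
                if a == b:
                    violations.append(f"block {i}: self-pair {a}")
    else:
        raise TypeError(f"not a design: {type(design)!r}")
    return {"valid": not violations, "violations": violations}


def _dummy_matrix(codes: list[str]) -> np.ndarray:
    """(n_states, 20) dimension-level dummy matrix (levels 2..5 per dimension)."""
    X = np.zeros((len(codes), 20))
    for i, code in enumerate(codes):
        for d, ch in enumerate(code):
            level = int(ch)
            if level >= 2:
                X[i, d * 4 + level - 2] = 1.0
    return X


def _random_state(rng: np.random.Generator, level_sum: int) -> str:
    """Draw a uniform state with the given total severity (sum of levels)."""
    while True:
        levels = rng.integers(1, 6, size=5)
        if levels.sum() == level_sum:
            return "".join(map(str, levels))


def generate_ctto_design(seed: int) -> CTTODesign:
    """Generate a synthetic cTTO design satisfying all structural constraints.

    80 filler states are drawn across severity strata (level sums spread over
    6..24) so that every dimension-level occurs in the universe; each of the
    five very mild states is used in two blocks; 55555 appears in every block.
    The result is deterministic per seed and its 20-column dummy design matrix
    has full column rank.
    """
    rng = np.random.default_rng(seed)
    for _ in range(100):  # redraw until identifiable (virtually always first try)
        taken = set(MILD_STATES) | {WORST_STATE}
        fillers: list[str] = []
        # 80 distinct fillers: level sums cycle over a mid-severity spread
        # (sum 6 is excluded: its only states are the reserved very mild ones)
        sums = [7 + (k % 18) for k in range(80)]
        for s in sums:
            while True:
                code = _random_state(rng, s)
                if code not in taken:
                    taken.add(code)
                    fillers.append(code)
                    break
        universe = sorted(taken)
        if np.linalg.matrix_rank(_dummy_matrix(universe)) == 20:
            break
    rng.shuffle(fillers)  # type: ignore[arg-type]
    blocks = []
    for i in range(10):
        block = [MILD_STATES[i % 5], WORST_STATE] + fillers[i * 8 : (i + 1) * 8]
        blocks.append(block)
    design = CTTODesign(blocks)
    report = validate_design(design)
    assert report["valid"], report["violations"]
    return design


def generate_dce_design(seed: int) -> DCEDesign:
    """Generate a synthetic DCE design: 28 blocks of 7 distinct state pairs."""
    rng = np.random.default_rng(seed)
    blocks: list[list[tuple[str, str]]] = []
    seen: set[tuple[str, str]] = set()
    for _ in range(28):
        block: list[tuple[str, str]] = []
        while len(block) < 7:
            a = "".join(map(str, rng.integers(1, 6, size=5)))
            b = "".join(map(str, rng.integers(1, 6, size=5)))
            if a != b and (a, b) not in seen:
                seen.add((a, b))
                block.append((a, b))
        blocks.append(block)
    return DCEDesign(blocks)


# -- delimited-text interfaces ----------------------------------------------


def write_ctto_design(design: CTTODesign, path) -> None:
    rows = [
        {"block": i, "state_code": s} for i, block in enumerate(design.blocks) for s in block
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_ctto_design(path) -> CTTODesign:
    df = pd.read_csv(path, dtype={"state_code": str})
    blocks = [
        df.loc[df["block"] == b, "state_code"].tolist() for b in sorted(df["block"].unique())
    ]
    return CTTODesign(blocks)


def write_dce_design(design: DCEDesign, path) -> None:
    rows = [
        {"block": i, "state_a": a, "state_b": b}
        for i, block in enumerate(design.blocks)
        for a, b in block
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_dce_design(path) -> DCEDesign:
    df = pd.read_csv(path, dtype={"state_a": str, "state_b": str})
    blocks = [
        list(zip(g["state_a"], g["state_b"]))
        for _, g in df.groupby("block", sort=True)
    ]
    return DCEDesign(blocks)
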