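"""State space of the multimorbidity Markov model.

The model tracks four chronic conditions — type 2 diabetes mellitus (DM),
coronary heart disease (CHD), stroke and colorectal cancer (CRC) — plus
comorbid depression and death.  An alive state is a subset of the four
conditions together with a depressed / not-depressed flag; the empty subset
is the healthy "at risk" state.  This yields 2**4 * 2 = 32 alive states and
one absorbing dead state, 33 in total.  Collapsing the depression split
gives 17 "main" states: at risk, dead, and the 15 non-empty condition
combinations.

States are ordered deterministically: condition subsets by number of
conditions then lexicographically by name, the not-depressed half before the
depressed half within each subset, and DEAD last.  State names are stable
strings such as ``"AT_RISK|nodep"``, ``"DM+CHD|dep"`` and ``"DEAD"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical condition order; bit i of a state mask flags DISEASES[i].
DISEASES: tuple[str, ...] = ("DM", "CHD", "STROKE", "CRC")

N_DISEASES = len(DISEASES)
N_MASKS = 1 << N_DISEASES  # 16 condition subsets, mask 0 = at risk


def mask_name(mask: int) -> str:
    """Human-readable name of a condition subset (``"AT_RISK"`` for mask 0)."""
    if mask == 0:
        return "AT_RISK"
    return "+".join(d for i, d in enumerate(DISEASES) if mask >> i & 1)


def mask_diseases(mask: int) -> tuple[str, ...]:
    return tuple(d for i, d in enumerate(DISEASES) if mask >> i & 1)


def _ordered_masks() -> list[int]:
    def key(mask: int) -> tuple[int, tuple[str, ...]]:
        return (bin(mask).count("1"), mask_diseases(mask))

    return sorted(range(N_MASKS), key=key)


@dataclass(frozen=True)
class StateSpace:
    """Ordered 33-state space with index lookups and vectorised attributes."""

    names: tuple[str, ...]
    masks: np.ndarray  # condition mask per state; -1 for DEAD
    depressed: np.ndarray  # bool per state; False for DEAD
    index: dict[str, int] = field(repr=False)

    @property
    def n_states(self) -> int:
        return len(self.names)

    @property
    def dead_index(self) -> int:
        return self.n_states - 1

    @property
    def alive_slice(self) -> slice:
        return slice(0, self.dead_index)

    def state_index(self, mask: int, depressed: bool) -> int:
        return self.index[f"{mask_name(mask)}|{'dep' if depressed else 'nodep'}"]

    def alive_indices(self, mask: int) -> tuple[int, int]:
        """(not-depressed, depressed) state indices for a condition subset."""
        return self.state_index(mask, False), self.state_index(mask, True)

    def disease_counts(self) -> np.ndarray:
        """Number of conditions per state (0 for DEAD; use masks to exclude)."""
        return np.where(self.masks >= 0, [bin(m & 0xF).count("1") for m in np.maximum(self.masks, 0)], 0)


def build_state_space() -> StateSpace:
    """Build the canonical 33-state space.

    Returns 32 alive states (16 condition subsets x depression flag) followed
    by the absorbing DEAD state.
    """
    names: list[str] = []
    masks: list[int] = []
    dep: list[bool] = []
    for mask in _ordered_masks():
        for depressed in (False, True):
            names.append(f"{mask_name(mask)}|{'dep' if depressed else 'nodep'}")
            masks.append(mask)
            dep.append(depressed)
    names.append("DEAD")
    masks.append(-1)
    dep.append(False)
    return StateSpace(
        names=tuple(names),
        masks=np.asarray(masks, dtype=np.int64),
        depressed=np.asarray(dep, dtype=bool),
        index={name: i for i, name in enumerate(names)},
    )


def main_state_count(space: StateSpace) -> int:
    """Number of "main" states: condition subsets plus dead (17)."""
    return N_MASKS + 1


def diseased_main_state_count(space: StateSpace) -> int:
    """Non-empty condition combinations (15)."""
    return N_MASKS - 1
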