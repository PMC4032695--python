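"""Time-dependent fuzzy division of the flow field.

The frame is split into four quadrant cells (C1 upper-left, C2
upper-right, C3 lower-left, C4 lower-right).  The location of the
maximal speed is fuzzified by triangular membership functions peaking at
the cell centers; memberships are accumulated over time with a memory
coefficient ``eta = +-1/(k + beta)`` where ``k`` counts frames since the
winner cell last changed.  The aggregated upper/lower-limb scores drive
the defuzzification gate that restricts candidate action classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .flow import FlowField, flow_speed

__all__ = ["FlowDivision", "FuzzyParams", "MembershipState", "LimbScores",
           "cell_memberships", "temporal_update", "limb_scores",
           "gate_actions", "triangular"]

CELLS = ("C1", "C2", "C3", "C4")


def triangular(x: float, left: float, peak: float, right: float) -> float:
    """Piecewise-linear triangle: 0 at/outside [left, right], 1 at peak."""
    if x <= left or x >= right:
        return 0.0
    if x == peak:
        return 1.0
    if x < peak:
        return (x - left) / (peak - left)
    return (right - x) / (right - peak)


@dataclass(frozen=True)
class FlowDivision:
    """Quadrant partition of an H x W frame with center-peaked triangles."""
    height: int
    width: int

    def cell_of(self, row: int, col: int) -> str:
        upper = row < self.height / 2
        left = col < self.width / 2
        if upper:
            return "C1" if left else "C2"
        return "C3" if left else "C4"

    def column_membership(self, col: float) -> tuple[float, float]:
        """(left-cells, right-cells) triangle values for a column."""
        w = self.width
        return (triangular(col, 0.0, w / 4.0, w / 2.0),
                triangular(col, w / 2.0, 3.0 * w / 4.0, float(w)))

    def row_membership(self, row: float) -> tuple[float, float]:
        """(upper-cells, lower-cells) triangle values for a row."""
        h = self.height
        return (triangular(row, 0.0, h / 4.0, h / 2.0),
                triangular(row, h / 2.0, 3.0 * h / 4.0, float(h)))


@dataclass(frozen=True)
class FuzzyParams:
    tau: float = 0.1          # frame time (s), a camera parameter
    beta: float = 2.0
    beta_prime: float | None = None
    n_max: int = 3            # cap on k, the frames-since-change counter
    margin: float = 0.05

    def __post_init__(self):
        bp = self.beta if self.beta_prime is None else self.beta_prime
        if self.beta <= 0 or bp <= 0:
            raise ValueError("beta and beta_prime must be positive "
                             "(k + beta must never vanish for k >= 0)")
        if self.n_max < 0:
            raise ValueError("n_max must be >= 0")

    @property
    def bprime(self) -> float:
        return self.beta if self.beta_prime is None else self.beta_prime


@dataclass
class MembershipState:
    """Accumulated memberships, memory counter and current winner cell."""
    mu_tilde: dict[str, float] = field(
        default_factory=lambda: {c: 0.0 for c in CELLS})
    k: int = 0
    winner: str | None = None
    params: FuzzyParams = field(default_factory=FuzzyParams)

    def copy(self) -> "MembershipState":
        return MembershipState(mu_tilde=dict(self.mu_tilde), k=self.k,
                               winner=self.winner, params=self.params)


@dataclass(frozen=True)
class LimbScores:
    mu_upper: float
    mu_lower: float
    mu_left: float | None = None
    mu_right: float | None = None


def cell_memberships(flow: FlowField, division: FlowDivision,
                     ) -> tuple[dict[str, float], str | None]:
    """Instantaneous per-cell memberships from the fastest pixel.

    Locates the speed argmax (ties: smallest row, then col), evaluates the
    four triangles over its column and row, and combines per cell with a
    max (column component vs row component).  All-zero flow returns
    uniform 0.25 memberships and no winner.
    """
    speed = flow_speed(flow)
    if speed.shape != (division.height, division.width):
        raise ValueError("flow shape does not match division")
    if not np.any(speed > 0):
        return {c: 0.25 for c in CELLS}, None
    idx = np.unravel_index(np.argmax(speed), speed.shape)  # first == tiebreak
    row, col = int(idx[0]), int(idx[1])
    mx_left, mx_right = division.column_membership(col)
    my_up, my_down = division.row_membership(row)
    mu = {
        "C1": max(mx_left, my_up),
        "C2": max(mx_right, my_up),
        "C3": max(mx_left, my_down),
        "C4": max(mx_right, my_down),
    }
    winner = division.cell_of(row, col)
    return mu, winner


def temporal_update(state: MembershipState, mu_now: dict[str, float],
                    winner_now: str | None = None) -> MembershipState:
    """One step of the memory-coefficient accumulation.

    The winner cell (max instantaneous membership, or the located cell if
    given) gets ``mu~ += eta (1 - mu~)`` with ``eta = 1/(k+beta)`` while its
    instantaneous membership sustains the stored value, and
    ``eta = -1/(k+beta')`` when the evidence drops below it; non-winner
    cells decay toward zero at rate ``1/(k+beta')``.  (The branch
    condition is stated ambiguously in the source formulation; this
    reading is the one under which accumulated memberships can actually
    grow from a cold start and drive the gate.)  ``k`` increments (capped at ``N``) while the
    winner persists and resets on a change.  Pure function: the input
    state is not mutated.
    """
    p = state.params
    new = state.copy()
    if winner_now is None:
        vals = [mu_now[c] for c in CELLS]
        if max(vals) - min(vals) < 1e-12:
            winner_now = state.winner  # degenerate frame: keep the winner
        else:
            winner_now = CELLS[int(np.argmax(vals))]
    if winner_now is None:
        return new  # cold start on a degenerate frame: nothing to update
    if winner_now == state.winner:
        new.k = min(state.k + 1, p.n_max)
    else:
        new.k = 0
        new.winner = winner_now
    k = new.k
    for c in CELLS:
        stored = state.mu_tilde[c]
        if c == winner_now:
            if mu_now[c] >= stored:
                eta = 1.0 / (k + p.beta)
            else:
                eta = -1.0 / (k + p.bprime)
            val = stored + eta * (1.0 - stored)
        else:
            val = stored + (1.0 / (k + p.bprime)) * (0.0 - stored)
        new.mu_tilde[c] = float(np.clip(val, 0.0, 1.0))
    return new


def limb_scores(state: MembershipState,
                enable_left_right: bool = False) -> LimbScores:
    """Aggregate cell memberships into limb-level flow scores."""
    mt = state.mu_tilde
    upper = max(mt["C1"], mt["C2"])
    lower = max(mt["C3"], mt["C4"])
    if enable_left_right:
        return LimbScores(mu_upper=upper, mu_lower=lower,
                          mu_left=max(mt["C1"], mt["C3"]),
                          mu_right=max(mt["C2"], mt["C4"]))
    return LimbScores(mu_upper=upper, mu_lower=lower)


def gate_actions(scores: LimbScores, class_groups: dict[str, str],
                 margin: float = 0.05) -> set[str]:
    """Defuzzification gate: restrict classes to the dominant limb group.

    Returns only the dominant group's classes when the upper/lower score
    gap exceeds ``margin``; under ambiguity every class stays eligible.
    Never returns an empty set.
    """
    if margin < 0:
        raise ValueError("margin must be >= 0")
    gap = scores.mu_upper - scores.mu_lower
    if gap > margin:
        allowed = {a for a, g in class_groups.items() if g == "upper"}
    elif gap < -margin:
        allowed = {a for a, g in class_groups.items() if g == "lower"}
    else:
        allowed = set(class_groups)
    return allowed if allowed else set(class_groups)
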