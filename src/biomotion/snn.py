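"""Synergetic (Haken-style) prototype classifier.

Samples are centered, unit-norm flattened frames.  Prototypes form the
columns of ``V``; classification projects a test sample onto adjoint
rows — either the Moore-Penrose pseudoinverse (biorthogonal: ``V+ V =
I``) or the MPOD-penalized class-row variant

    v_p+ = E (V^T V + P1*O + P2*I)^(-1) V^T

with ``O`` the all-ones matrix and ``E`` a block row-selector summing
each class's columns.  "Melting" synthesizes several samples into one
template via the single-class MPOD row.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import qr

__all__ = ["SampleVector", "PrototypeBank", "OrderParameters",
           "normalize_sample", "moore_penrose_adjoint", "mpod_adjoint",
           "order_parameters", "melt", "build_action_prototypes",
           "RankDeficiencyError"]


class RankDeficiencyError(np.linalg.LinAlgError):
    """Prototype matrix has linearly dependent columns."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(
            f"prototype matrix is rank deficient; offending columns: "
            f"{self.columns}")


@dataclass
class SampleVector:
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()

    def __len__(self):
        return self.values.size


@dataclass
class PrototypeBank:
    V: np.ndarray               # n x M, columns are normalized prototypes
    V_adj: np.ndarray           # adjoint (M x n, or classes x n for MPOD)
    labels: list[str]           # one label per adjoint row
    penalty: tuple[float, float] | None = None


@dataclass
class OrderParameters:
    epsilon: np.ndarray
    winner: int
    label: str | None = None


def normalize_sample(image: np.ndarray) -> SampleVector:
    """Flatten (row-major), remove the mean and scale to unit l2 norm."""
    v = np.asarray(image, dtype=float).ravel().copy()
    v -= v.mean()
    norm = np.linalg.norm(v)
    if norm < 1e-12:
        raise ValueError("constant image: zero vector after centering")
    return SampleVector(v / norm)


def _as_matrix(V) -> np.ndarray:
    V = np.asarray(V, dtype=float)
    if V.ndim != 2:
        raise ValueError("prototype matrix must be 2-D")
    return V


def moore_penrose_adjoint(V: np.ndarray) -> np.ndarray:
    """Biorthogonal adjoint ``(V^T V)^(-1) V^T`` of a full-column-rank V."""
    V = _as_matrix(V)
    n, M = V.shape
    rank = np.linalg.matrix_rank(V)
    if rank < M:
        # pivoted QR names which columns are (numerically) dependent
        _, _, piv = qr(V, mode="economic", pivoting=True)
        offending = sorted(int(j) for j in piv[rank:])
        raise RankDeficiencyError(offending)
    return np.linalg.solve(V.T @ V, V.T)


def _enhanced_identity(group_sizes: list[int]) -> np.ndarray:
    """Block row-selector: one row of ones over each class's columns."""
    M = int(sum(group_sizes))
    E = np.zeros((len(group_sizes), M))
    start = 0
    for gi, g in enumerate(group_sizes):
        E[gi, start:start + g] = 1.0
        start += g
    return E


def mpod_adjoint(V: np.ndarray, P1: float, P2: float,
                 group_sizes: list[int]) -> np.ndarray:
    """MPOD-penalized class-row adjoint ``E (V^T V + P1*O + P2*I)^(-1) V^T``."""
    V = _as_matrix(V)
    n, M = V.shape
    if P1 < 0 or P2 < 0:
        raise ValueError("penalties must be >= 0")
    if sum(group_sizes) != M:
        raise ValueError(f"group sizes {group_sizes} do not sum to {M} columns")
    G = V.T @ V + P1 * np.ones((M, M)) + P2 * np.eye(M)
    try:
        core = np.linalg.solve(G, V.T)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "regularized Gram matrix is singular; increase P2") from exc
    cond = np.linalg.cond(G)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            f"regularized Gram matrix is numerically singular "
            f"(cond={cond:.3g}); increase P2")
    return _enhanced_identity(group_sizes) @ core


def order_parameters(q: SampleVector | np.ndarray,
                     bank: PrototypeBank) -> OrderParameters:
    """Project a sample onto the adjoint rows; winner = argmax epsilon."""
    vec = q.values if isinstance(q, SampleVector) else np.asarray(q, float).ravel()
    if vec.size != bank.V_adj.shape[1]:
        raise ValueError(
            f"sample length {vec.size} != prototype length {bank.V_adj.shape[1]}")
    eps = bank.V_adj @ vec
    winner = int(np.argmax(eps))  # first occurrence == lowest-index tie-break
    label = bank.labels[winner] if bank.labels else None
    return OrderParameters(epsilon=eps, winner=winner, label=label)


def melt(samples: list[SampleVector], P1: float = 0.0,
         P2: float = 0.1) -> SampleVector:
    """Synthesize several normalized samples into one template.

    Builds the single-class MPOD row over the sample matrix, which lives
    in sample space, and renormalizes it.  A lone sample melts to itself.
    """
    if len(samples) == 0:
        raise ValueError("melt requires at least one sample")
    lengths = {len(s) for s in samples}
    if len(lengths) != 1:
        raise ValueError(f"samples differ in length: {lengths}")
    if len(samples) == 1:
        return SampleVector(samples[0].values.copy())
    V = np.stack([s.values for s in samples], axis=1)
    row = mpod_adjoint(V, P1, P2, [V.shape[1]])[0]
    return normalize_sample(row)


def build_action_prototypes(training_map: dict[str, list[list[np.ndarray]]],
                            P1: float = 0.0, P2: float = 0.1,
                            ) -> dict[str, dict[str, list[SampleVector]]]:
    """Two-stage melting of an action -> snippets -> subject-frames map.

    Stage 1 melts each snippet across subjects into a snippet prototype
    ``P_s``; stage 2 melts the snippet prototypes into the final action
    prototype ``F_t``.  Both are retained:
    ``{action: {"snippets": [P_1..P_S], "final": [F_t]}}``.
    """
    out: dict[str, dict[str, list[SampleVector]]] = {}
    for action in sorted(training_map):
        snippets = training_map[action]
        if len(snippets) == 0:
            raise ValueError(f"action {action!r} has no snippets")
        ps: list[SampleVector] = []
        for si, subject_frames in enumerate(snippets):
            if len(subject_frames) == 0:
                raise ValueError(
                    f"action {action!r}, snippet {si} has no subject frames")
            ps.append(melt([normalize_sample(f) for f in subject_frames],
                           P1=P1, P2=P2))
        ft = melt(ps, P1=P1, P2=P2)
        out[action] = {"snippets": ps, "final": [ft]}
    return out
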