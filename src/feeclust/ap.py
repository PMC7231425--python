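"""Affinity propagation baseline.

Classic message passing between data points on a full similarity matrix:
responsibilities ``R(i,k) = S(i,k) - max_{j != k} (A(i,j) + S(i,j))`` and
availabilities ``A(i,k) = min(0, R(k,k) + sum_{j not in {i,k}} max(0, R(j,k)))``
for ``i != k`` with ``A(k,k) = sum_{j != k} max(0, R(j,k))``, damped by a
factor ``lambda`` in ``[0, 1)``.  After convergence each point's exemplar is
``argmax_k (A(i,k) + R(i,k))``; the configuration is then repaired to
validity by keeping the self-electing points as exemplars and reassigning
everyone else to their most similar exemplar.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data import SimilarityMatrix
from .metrics import ClusteringReport

__all__ = ["MessageState", "update_responsibility", "update_availability", "run_ap"]


@dataclass(frozen=True)
class MessageState:
    """Responsibility/availability matrices plus the damping factor."""

    r: np.ndarray
    a: np.ndarray
    damping: float
    iteration: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.damping <= 1.0):
            raise ValueError("damping must lie in [0, 1]")
        if self.r.shape != self.a.shape or self.r.ndim != 2:
            raise ValueError("R and A must be equal-shape square matrices")

    @classmethod
    def zeros(cls, n: int, damping: float = 0.5) -> "MessageState":
        return cls(r=np.zeros((n, n)), a=np.zeros((n, n)), damping=damping)


def update_responsibility(s: SimilarityMatrix, state: MessageState) -> MessageState:
    """One damped responsibility update (full similarity only)."""
    if s.is_compressed:
        raise ValueError("affinity propagation needs a full similarity matrix")
    sa = state.a + s.values
    n = sa.shape[0]
    rows = np.arange(n)
    j1 = sa.argmax(axis=1)
    m1 = sa[rows, j1]
    sa2 = sa.copy()
    sa2[rows, j1] = -np.inf
    m2 = sa2.max(axis=1)
    r_new = s.values - m1[:, None]
    r_new[rows, j1] = s.values[rows, j1] - m2
    lam = state.damping
    r = lam * state.r + (1.0 - lam) * r_new
    if not np.isfinite(r).all():
        raise FloatingPointError("non-finite responsibility message")
    return MessageState(r=r, a=state.a, damping=lam, iteration=state.iteration)


def update_availability(state: MessageState) -> MessageState:
    """One damped availability update."""
    r = state.r
    rp = np.maximum(r, 0.0)
    np.fill_diagonal(rp, 0.0)
    colsums = rp.sum(axis=0)  # sum_{j != k} max(0, R(j,k))
    a_new = np.minimum(0.0, r.diagonal()[None, :] + colsums[None, :] - rp)
    np.fill_diagonal(a_new, colsums)
    lam = state.damping
    a = lam * state.a + (1.0 - lam) * a_new
    if not np.isfinite(a).all():
        raise FloatingPointError("non-finite availability message")
    return MessageState(r=r, a=a, damping=lam, iteration=state.iteration)


def _extract_configuration(
    s: SimilarityMatrix, state: MessageState
) -> tuple[np.ndarray, np.ndarray]:
    """Exemplar set = self-electing points under argmax(A+R); everyone else
    is repaired to their most similar exemplar."""
    ar = state.a + state.r
    n = ar.shape[0]
    choice = ar.argmax(axis=1)
    exemplars = np.flatnonzero(choice == np.arange(n))
    if exemplars.size == 0:
        # no point elects itself yet: fall back to the best single exemplar
        exemplars = np.array([int(s.values.sum(axis=0).argmax())])
    e = exemplars[s.values[:, exemplars].argmax(axis=1)]
    e[exemplars] = exemplars
    return e, exemplars


def run_ap(
    s: SimilarityMatrix,
    damping: float = 0.5,
    max_iter: int = 1000,
    conv_window: int = 50,
    seed: int | None = None,
) -> ClusteringReport:
    """Iterate message updates until the exemplar set is stable.

    Convergence means the extracted exemplar set is unchanged for
    ``conv_window`` consecutive sweeps.  If ``max_iter`` is exhausted first,
    the best configuration seen (by the exemplar objective
    ``sum_i S(i, E(i))``) is returned and a warning is flagged.
    """
    if not (0.0 <= damping < 1.0):
        raise ValueError("damping must lie in [0, 1)")
    if s.is_compressed:
        raise ValueError("affinity propagation needs a full similarity matrix")
    n = s.n_rows
    state = MessageState.zeros(n, damping)
    rows = np.arange(n)
    best_obj = -np.inf
    best: tuple[np.ndarray, np.ndarray] | None = None
    prev_exemplars: np.ndarray | None = None
    stable = 0
    converged = False
    iterations = 0
    for it in range(1, max_iter + 1):
        state = update_responsibility(s, state)
        state = update_availability(state)
        state = MessageState(
            r=state.r, a=state.a, damping=damping, iteration=it
        )
        e, exemplars = _extract_configuration(s, state)
        obj = float(s.values[rows, e].sum())
        if obj > best_obj:
            best_obj = obj
            best = (e, exemplars)
        if prev_exemplars is not None and np.array_equal(exemplars, prev_exemplars):
            stable += 1
        else:
            stable = 0
        prev_exemplars = exemplars
        iterations = it
        if stable >= conv_window:
            converged = True
            break

    report_warnings: list[str] = []
    if not converged:
        msg = f"no convergence within {max_iter} iterations; returning best-so-far"
        report_warnings.append(msg)
        warnings.warn(msg, RuntimeWarning, stacklevel=2)
    assert best is not None
    e, exemplars = best
    label_of = {int(r): k for k, r in enumerate(exemplars, start=1)}
    labels = np.array([label_of[int(r)] for r in e])
    return ClusteringReport(
        labels=labels,
        exemplars=exemplars,
        objective=best_obj,
        meta={
            "algorithm": "ap",
            "seed": seed,
            "iterations": iterations,
            "converged": converged,
            "damping": damping,
            "warnings": report_warnings,
        },
    )
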