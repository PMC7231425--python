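"""Enhanced alpha-expansion-move optimisation of the exemplar objective.

The objective maximized here is

    max_E  sum_i S(i, E(i))

over assignments ``E`` of each point to an exemplar drawn from a candidate
list, subject to *validity*: anything chosen as someone's exemplar must be
its own exemplar.  Diagonal (preference) terms are included, so larger
preferences favour more exemplars.  Validity is enforced structurally —
every move is constructed valid-by-design, which is equivalent to an
infinite pairwise penalty on invalid pairs but immune to overflow.

Local search visits each candidate ``alpha`` in ascending row order:

* ``alpha`` currently an exemplar -> *removal* move: every member of its
  cluster (alpha included, which surrenders the preference term) falls back
  to its second-best exemplar.
* ``alpha`` currently not an exemplar -> *addition* move: alpha becomes an
  exemplar and each existing cluster independently chooses the best of
  (a) dissolving entirely, sending its exemplar and members to their best
  remaining exemplar or to alpha, (b) migrating exactly the members that
  prefer alpha, or (c) staying put.  A ``global`` combination rule that
  forces one collective choice across clusters is kept as an option.

Each :class:`MoveEvaluation` reports the *exact* objective change its
assignments would cause, so accepted moves (strictly positive reduction)
yield a monotone, finitely terminating search.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .data import SimilarityMatrix
from .metrics import ClusteringReport

__all__ = [
    "ExemplarConfig",
    "MoveEvaluation",
    "config_objective",
    "second_exemplar",
    "evaluate_removal",
    "evaluate_addition",
    "apply_move",
    "sweep",
    "run_eem",
]

NEG_INF = float("-inf")


@dataclass(frozen=True)
class ExemplarConfig:
    """A per-point exemplar assignment with its induced exemplar set.

    ``assignments[i]`` is the dataset row serving as point ``i``'s exemplar.
    The configuration is *valid* when every assigned exemplar is
    self-assigned; invalid configurations carry objective ``-inf``.
    """

    assignments: np.ndarray
    exemplar_set: np.ndarray
    objective: float
    valid: bool

    @classmethod
    def from_assignments(
        cls, s: SimilarityMatrix, assignments: Sequence[int] | np.ndarray
    ) -> "ExemplarConfig":
        e = np.asarray(assignments, dtype=int).copy()
        if e.size != s.n_rows:
            raise ValueError("one assignment per dataset row required")
        cols = s.cols(e)  # raises if an assignment is not a candidate
        exemplar_set = np.unique(e)
        valid = bool(np.array_equal(e[exemplar_set], exemplar_set))
        if valid:
            objective = float(s.values[np.arange(e.size), cols].sum())
        else:
            objective = NEG_INF
        e.setflags(write=False)
        return cls(
            assignments=e,
            exemplar_set=exemplar_set,
            objective=objective,
            valid=valid,
        )

    @property
    def n_clusters(self) -> int:
        return self.exemplar_set.size

    def members_of(self, exemplar: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == exemplar)


def config_objective(
    s: SimilarityMatrix,
    assignments: Sequence[int] | np.ndarray,
    raise_on_invalid: bool = False,
) -> float:
    """Objective ``sum_i S(i, E(i))`` of a configuration; ``-inf`` (or an
    error, per flag) when validity is violated."""
    cfg = ExemplarConfig.from_assignments(s, assignments)
    if not cfg.valid and raise_on_invalid:
        raise ValueError("configuration violates exemplar validity")
    return cfg.objective


@dataclass(frozen=True)
class MoveEvaluation:
    """A candidate move and its exact objective change.

    ``new_assignments`` maps only the rows whose exemplar would change;
    ``reduction`` equals the objective after applying them minus the
    objective before (so every move is self-certifying).
    """

    alpha: int
    case: str  # "removal" | "addition"
    reduction: float
    new_assignments: dict[int, int]


def _best_among(
    s: SimilarityMatrix, rows: np.ndarray, candidate_rows: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per row, the best candidate among ``candidate_rows`` (which must be
    ascending so that argmax ties resolve to the lowest row index)."""
    v = s.values[np.ix_(rows, s.cols(candidate_rows))]
    j = v.argmax(axis=1)
    return v[np.arange(rows.size), j], candidate_rows[j]


def second_exemplar(
    s: SimilarityMatrix, config: ExemplarConfig, alpha: int
) -> dict[int, int]:
    """Best alternative exemplar for each member of alpha's cluster.

    For every point currently assigned to ``alpha`` (alpha itself included)
    this returns the most similar exemplar among the remaining ones; ties go
    to the lowest row index.
    """
    if alpha not in config.exemplar_set:
        raise ValueError(f"row {alpha} is not an exemplar")
    if config.n_clusters < 2:
        raise ValueError("cannot remove last exemplar")
    others = config.exemplar_set[config.exemplar_set != alpha]
    members = config.members_of(alpha)
    _, best_rows = _best_among(s, members, others)
    return {int(i): int(r) for i, r in zip(members, best_rows)}


def evaluate_removal(
    s: SimilarityMatrix, config: ExemplarConfig, alpha: int
) -> MoveEvaluation:
    """Energy reduction of retiring exemplar alpha.

    The raw reduction sums, over alpha's cluster, the similarity to the
    second exemplar minus the similarity to alpha; alpha's own term trades
    the preference for its second exemplar.  Clamped at zero: a
    non-improving removal is returned as an empty move.
    """
    if alpha not in config.exemplar_set:
        raise ValueError(f"row {alpha} is not an exemplar")
    if config.n_clusters < 2:
        raise ValueError("cannot remove last exemplar")
    others = config.exemplar_set[config.exemplar_set != alpha]
    members = config.members_of(alpha)
    best_vals, best_rows = _best_among(s, members, others)
    current = s.values[members, s.col(alpha)]
    raw = float(best_vals.sum() - current.sum())
    if raw > 0:
        moves = {int(i): int(r) for i, r in zip(members, best_rows)}
        return MoveEvaluation(int(alpha), "removal", raw, moves)
    return MoveEvaluation(int(alpha), "removal", 0.0, {})


def evaluate_addition(
    s: SimilarityMatrix,
    config: ExemplarConfig,
    alpha: int,
    r2_combination: str = "per_cluster",
) -> MoveEvaluation:
    """Energy reduction of promoting candidate alpha to an exemplar.

    alpha's own term trades its current similarity for the preference.  Each
    existing cluster then contributes the best of three options: dissolve
    (the exemplar and all members leave for their best remaining exemplar or
    alpha), migrate (exactly the members preferring alpha switch to it), or
    no change.  With ``r2_combination='global'`` one option is chosen
    collectively for all clusters instead (all dissolve vs. all migrate vs.
    nothing).

    After the per-cluster choices, members of dissolved clusters are
    re-targeted at the exemplars that actually survive, and the returned
    reduction is the exact objective delta of those final assignments.
    """
    if r2_combination not in ("per_cluster", "global"):
        raise ValueError("r2_combination must be 'per_cluster' or 'global'")
    if alpha in config.exemplar_set:
        raise ValueError(f"row {alpha} is already an exemplar")
    col_alpha = s.col(alpha)  # raises if alpha is not a candidate
    e = config.assignments
    exemplars = config.exemplar_set  # ascending
    sim_alpha = s.values[:, col_alpha]

    # Per point: best and runner-up similarity over the current exemplars,
    # so that "best excluding e" is O(1) per cluster below.
    ex_cols = s.cols(exemplars)
    v = s.values[:, ex_cols]
    n = v.shape[0]
    best1_j = v.argmax(axis=1)
    rows = np.arange(n)
    best1 = v[rows, best1_j]
    if exemplars.size > 1:
        v2 = v.copy()
        v2[rows, best1_j] = NEG_INF
        best2 = v2.max(axis=1)
    else:
        best2 = np.full(n, NEG_INF)

    per_cluster: list[dict] = []
    for k, ex in enumerate(exemplars):
        members = config.members_of(ex)
        members = members[members != alpha]
        cur = s.values[members, ex_cols[k]]
        # best among remaining exemplars and alpha
        alt = np.where(best1_j[members] == k, best2[members], best1[members])
        dissolve_gain = float(np.maximum(alt, sim_alpha[members]).sum() - cur.sum())
        mig = (sim_alpha[members] > cur) & (members != ex)
        migrate_gain = float((sim_alpha[members][mig] - cur[mig]).sum())
        per_cluster.append(
            {
                "exemplar": int(ex),
                "members": members,
                "dissolve_gain": dissolve_gain,
                "migrate_gain": migrate_gain,
                "movers": members[mig],
            }
        )

    if r2_combination == "per_cluster":
        for info in per_cluster:
            gains = np.array([0.0, info["migrate_gain"], info["dissolve_gain"]])
            info["choice"] = int(gains.argmax())  # ties: stay > migrate > dissolve
    else:
        totals = np.array(
            [
                0.0,
                sum(i["migrate_gain"] for i in per_cluster),
                sum(i["dissolve_gain"] for i in per_cluster),
            ]
        )
        choice = int(totals.argmax())
        for info in per_cluster:
            info["choice"] = choice

    dissolved = {i["exemplar"] for i in per_cluster if i["choice"] == 2}
    surviving = np.sort(
        np.append(exemplars[~np.isin(exemplars, list(dissolved))], alpha)
    )
    new: dict[int, int] = {int(alpha): int(alpha)}
    for info in per_cluster:
        if info["choice"] == 2:
            members = info["members"]
            if members.size:
                _, targets = _best_among(s, members, surviving)
                for i, r in zip(members, targets):
                    new[int(i)] = int(r)
        elif info["choice"] == 1:
            for i in info["movers"]:
                new[int(i)] = int(alpha)

    changed = np.array([i for i, r in new.items() if r != e[i]], dtype=int)
    if changed.size:
        new_rows = np.array([new[int(i)] for i in changed], dtype=int)
        reduction = float(
            s.values[changed, s.cols(new_rows)].sum()
            - s.values[changed, s.cols(e[changed])].sum()
        )
    else:
        reduction = 0.0
    return MoveEvaluation(int(alpha), "addition", reduction, new)


def apply_move(
    s: SimilarityMatrix, config: ExemplarConfig, move: MoveEvaluation
) -> ExemplarConfig:
    """Materialize a move into a fresh (validated) configuration."""
    e = config.assignments.copy()
    for i, r in move.new_assignments.items():
        e[i] = r
    return ExemplarConfig.from_assignments(s, e)


def sweep(
    s: SimilarityMatrix,
    config: ExemplarConfig,
    candidates: np.ndarray | None = None,
    r2_combination: str = "per_cluster",
    on_move: Callable[[MoveEvaluation, ExemplarConfig], None] | None = None,
) -> tuple[ExemplarConfig, bool]:
    """One pass over all candidates in ascending row order.

    A removal is evaluated when the candidate is an exemplar (unless it is
    the last one), an addition otherwise; moves are applied iff their
    reduction is strictly positive, so the objective never decreases.
    ``on_move`` observes every evaluation against the configuration it was
    evaluated on.
    """
    cand = s.candidate_map if candidates is None else np.asarray(candidates, int)
    improved = False
    for alpha in np.sort(cand):
        if alpha in config.exemplar_set:
            if config.n_clusters < 2:
                continue
            move = evaluate_removal(s, config, alpha)
        else:
            move = evaluate_addition(s, config, alpha, r2_combination)
        if on_move is not None:
            on_move(move, config)
        if move.reduction > 0:
            config = apply_move(s, config, move)
            improved = True
    return config, improved


def _best_single_exemplar_init(
    s: SimilarityMatrix, candidates: np.ndarray
) -> ExemplarConfig:
    """Deterministic start: the single candidate maximizing the one-cluster
    objective (its column sum, preference included)."""
    cand = np.sort(candidates)
    totals = s.values[:, s.cols(cand)].sum(axis=0)
    best = int(cand[int(totals.argmax())])
    e = np.full(s.n_rows, best, dtype=int)
    return ExemplarConfig.from_assignments(s, e)


def run_eem(
    s: SimilarityMatrix,
    candidates: np.ndarray | None = None,
    max_sweeps: int = 200,
    init: ExemplarConfig | None = None,
    seed: int | None = None,
    r2_combination: str = "per_cluster",
    on_move: Callable[[MoveEvaluation, ExemplarConfig], None] | None = None,
) -> ClusteringReport:
    """Run the move-based local search to convergence.

    The search is deterministic (``seed`` is recorded for provenance only):
    starting from ``init`` — by default the best single-exemplar
    configuration — sweeps repeat until none applies a move or
    ``max_sweeps`` is hit, in which case the best-so-far configuration is
    returned with a warning flag in the report metadata.
    """
    cand = s.candidate_map if candidates is None else np.asarray(candidates, int)
    if cand.size == 0:
        raise ValueError("empty candidate list")
    config = _best_single_exemplar_init(s, cand) if init is None else init
    if not config.valid:
        raise ValueError("initial configuration is invalid")
    trace = [config.objective]
    report_warnings: list[str] = []
    n_sweeps = 0
    converged = False
    for _ in range(max_sweeps):
        config, improved = sweep(s, config, cand, r2_combination, on_move)
        n_sweeps += 1
        trace.append(config.objective)
        if not improved:
            converged = True
            break
    if not converged:
        msg = f"no convergence within {max_sweeps} sweeps; returning best-so-far"
        report_warnings.append(msg)
        warnings.warn(msg, RuntimeWarning, stacklevel=2)

    exemplars = config.exemplar_set  # ascending -> cluster ids 1..K
    label_of = {int(r): k for k, r in enumerate(exemplars, start=1)}
    labels = np.array([label_of[int(r)] for r in config.assignments])
    return ClusteringReport(
        labels=labels,
        exemplars=exemplars,
        objective=config.objective,
        meta={
            "algorithm": "eem",
            "seed": seed,
            "sweeps": n_sweeps,
            "converged": converged,
            "objective_trace": trace,
            "warnings": report_warnings,
            "n_candidates": int(cand.size),
        },
    )
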