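"""Clustering performance indices and the shared result container.

Three indices are reported:

* ``ENERGY`` — sum over clusters of Euclidean distances from members to
  their exemplar (lower is better).  With missing features the rescaled
  partial squared distance is computed first and then square-rooted.  A
  squared variant is available for direct comparison with the similarity
  objective.
* ``NMI`` — normalized mutual information with geometric-mean
  normalization: ``I(U;V) / sqrt(H(U) H(V))`` in natural logs.
* ``accuracy`` — fraction of points correctly labelled after the optimal
  one-to-one mapping of cluster ids onto class ids, found by the Hungarian
  algorithm on the contingency table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import linear_sum_assignment

from .data import MaskedDataset, partial_sq_distance, penalized_sq_distances

__all__ = ["ClusteringReport", "energy", "nmi", "accuracy"]


@dataclass
class ClusteringReport:
    """Labels, exemplars and scores of a single clustering run.

    ``labels`` take values ``1..K`` and ``exemplars[k-1]`` is the dataset
    row serving as the exemplar of cluster ``k``.  Score fields are ``None``
    until computed (e.g. NMI/accuracy need ground-truth classes).
    """

    labels: np.ndarray
    exemplars: np.ndarray
    objective: float
    energy: float | None = None
    nmi: float | None = None
    accuracy: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.exemplars = np.asarray(self.exemplars, dtype=int)
        k = self.exemplars.size
        if k < 1:
            raise ValueError("at least one exemplar required")
        present = np.unique(self.labels)
        if not np.array_equal(present, np.arange(1, k + 1)):
            raise ValueError("labels must be surjective onto 1..K")

    @property
    def n_clusters(self) -> int:
        return self.exemplars.size

    def exemplar_of(self, i: int) -> int:
        return int(self.exemplars[self.labels[i] - 1])

    # -- serialization --------------------------------------------------
    def to_dict(self, include_timings: bool = False) -> dict:
        meta = dict(self.meta)
        if not include_timings:
            meta.pop("timings", None)
        return {
            "labels": self.labels.tolist(),
            "exemplars": self.exemplars.tolist(),
            "objective": self.objective,
            "energy": self.energy,
            "nmi": self.nmi,
            "accuracy": self.accuracy,
            "meta": meta,
        }

    def write_json(self, path: str | Path, include_timings: bool = False) -> None:
        Path(path).write_text(
            json.dumps(self.to_dict(include_timings), indent=2, sort_keys=True)
            + "\n"
        )

    def write_labels_tsv(self, path: str | Path) -> None:
        """One row per observation: index, cluster label, exemplar row."""
        lines = ["index\tlabel\texemplar"]
        for i, lab in enumerate(self.labels):
            lines.append(f"{i}\t{lab}\t{self.exemplar_of(i)}")
        Path(path).write_text("\n".join(lines) + "\n")


def energy(
    data: MaskedDataset,
    report: ClusteringReport,
    mode: str = "euclidean",
) -> float:
    """Within-cluster distance sum to exemplars.

    ``mode='euclidean'`` (default) sums unsquared distances; ``'squared'``
    sums the squared distances underlying the similarity matrix.
    """
    if mode not in ("euclidean", "squared"):
        raise ValueError("mode must be 'euclidean' or 'squared'")
    if report.labels.size != data.n:
        raise ValueError("labels do not match dataset size")
    for k, ex in enumerate(report.exemplars, start=1):
        if report.labels[ex] != k:
            raise ValueError(
                f"exemplar {ex} of cluster {k} does not carry its own label"
            )
    penalized: np.ndarray | None = None
    total = 0.0
    for i in range(data.n):
        ex = report.exemplar_of(i)
        if ex == i:
            continue
        shared = data.observed[i] & data.observed[ex]
        if shared.any():
            d2 = partial_sq_distance(
                data.values[i], data.values[ex], data.observed[i], data.observed[ex]
            )
        else:
            # no shared feature: fall back to the variance-penalized
            # distance the similarity matrices use for such pairs
            if penalized is None:
                penalized = penalized_sq_distances(data)
            d2 = float(penalized[i, ex])
        total += d2 if mode == "squared" else float(np.sqrt(d2))
    return total


def _contingency(labels: np.ndarray, classes: np.ndarray) -> np.ndarray:
    _, li = np.unique(labels, return_inverse=True)
    _, ci = np.unique(classes, return_inverse=True)
    table = np.zeros((li.max() + 1, ci.max() + 1), dtype=float)
    np.add.at(table, (li, ci), 1.0)
    return table


def nmi(labels, classes) -> float:
    """Normalized mutual information, geometric-mean normalization.

    Trivial edges: two single-group partitions agree perfectly (1); a
    single-group partition against a non-trivial one carries no information
    (0).  The convention ``0 * ln(0) = 0`` applies throughout.
    """
    labels = np.asarray(labels).ravel()
    classes = np.asarray(classes).ravel()
    if labels.size != classes.size:
        raise ValueError("label vectors must have equal length")
    if labels.size == 0:
        raise ValueError("empty label vectors")
    table = _contingency(labels, classes)
    n = labels.size
    if table.shape[0] == 1 and table.shape[1] == 1:
        return 1.0
    if table.shape[0] == 1 or table.shape[1] == 1:
        return 0.0
    ni = table.sum(axis=1)
    nj = table.sum(axis=0)
    nz = table > 0
    num = float(
        (table[nz] * np.log(n * table[nz] / np.outer(ni, nj)[nz])).sum()
    )
    den = float(np.sqrt((ni * np.log(ni / n)).sum() * (nj * np.log(nj / n)).sum()))
    if den == 0.0:
        return 0.0
    return num / den


def accuracy(labels, classes) -> float:
    """Hungarian-mapped clustering accuracy.

    The contingency table is zero-padded to a square so that an unequal
    number of clusters and classes still yields a one-to-one mapping.
    """
    labels = np.asarray(labels).ravel()
    classes = np.asarray(classes).ravel()
    if labels.size != classes.size:
        raise ValueError("label vectors must have equal length")
    table = _contingency(labels, classes)
    size = max(table.shape)
    padded = np.zeros((size, size))
    padded[: table.shape[0], : table.shape[1]] = table
    r, c = linear_sum_assignment(padded, maximize=True)
    return float(padded[r, c].sum() / labels.size)
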