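"""Feature matrices with missing entries and pairwise similarity construction.

Exemplar-based clustering operates on a similarity matrix
``S(i, j) = -||x_i - x_j||^2`` whose diagonal carries a shared *preference*
value ``p``: the larger the preference, the more points elect to become
exemplars (cluster centres that are themselves data points).  Here the
preference defaults to the median of the off-diagonal similarities, computed
once over the unordered pairs of the whole dataset.

Missing feature values are handled with the partial-distance strategy:
squared differences are summed over the features observed in *both* rows and
rescaled by ``D / |overlap|`` so distances involving incomplete rows remain
comparable to fully observed ones.  A pair of rows sharing no observed
feature has no defined distance: the pairwise primitive raises
:class:`EmptyOverlapError`.

Similarity matrices use a closely related *variance-penalized* distance
(see :func:`penalized_sq_distances`): squared differences over the shared
observed features plus one marginal feature variance per missing feature
per row.  The surcharge keeps point-to-exemplar assignment driven purely
by the observed coordinates while making incomplete rows expensive to
elect as exemplars, and it gives pairs with no shared features a finite,
deliberately large distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EmptyOverlapError",
    "MaskedDataset",
    "SimilarityMatrix",
    "partial_sq_distance",
    "pairwise_partial_sq_distances",
    "column_variances",
    "penalized_sq_distances",
    "median_preference",
    "build_similarity",
    "build_compressed_similarity",
    "zscore",
]


class EmptyOverlapError(ValueError):
    """Raised when two rows share no observed feature."""


@dataclass(frozen=True)
class MaskedDataset:
    """An N x D feature matrix plus a boolean observedness mask.

    ``observed[i, d]`` is True when feature ``d`` of row ``i`` was measured.
    Rows with an all-True mask row are *complete*; rows with at least one
    False entry are *incomplete*.  Every row must retain at least one
    observed feature, and observed cells must hold finite values.
    """

    values: np.ndarray
    observed: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if self.observed is None:
            observed = np.isfinite(values)
        else:
            observed = np.asarray(self.observed, dtype=bool)
        if observed.shape != values.shape:
            raise ValueError(
                f"mask shape {observed.shape} != values shape {values.shape}"
            )
        if values.shape[0] < 1 or values.shape[1] < 1:
            raise ValueError("dataset must have at least one row and one column")
        rows_empty = ~observed.any(axis=1)
        if rows_empty.any():
            bad = int(np.flatnonzero(rows_empty)[0])
            raise ValueError(f"row {bad} has no observed features")
        if not np.isfinite(values[observed]).all():
            raise ValueError("observed cells must be finite")
        values = values.copy()
        values[~observed] = np.nan  # missing cells carry no information
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "observed", observed.copy())
        self.values.setflags(write=False)
        self.observed.setflags(write=False)

    # -- basic geometry -------------------------------------------------
    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]

    @property
    def complete_idx(self) -> np.ndarray:
        """Rows whose mask row is all-True (ascending)."""
        return np.flatnonzero(self.observed.all(axis=1))

    @property
    def incomplete_idx(self) -> np.ndarray:
        """Rows with at least one unobserved feature (ascending)."""
        return np.flatnonzero(~self.observed.all(axis=1))

    @property
    def n_complete(self) -> int:
        return int(self.observed.all(axis=1).sum())

    @property
    def n_incomplete(self) -> int:
        return self.n - self.n_complete

    # -- construction ---------------------------------------------------
    @classmethod
    def from_values(cls, values: np.ndarray) -> "MaskedDataset":
        """Build from a matrix where NaN encodes a missing cell."""
        values = np.asarray(values, dtype=float)
        return cls(values=values, observed=np.isfinite(values))

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        mask_path: str | Path | None = None,
        sep: str | None = None,
    ) -> "MaskedDataset":
        """Read a numeric matrix (CSV/TSV; header and row-id column optional).

        NaN or empty cells are unobserved.  When ``mask_path`` is given it is
        read as a parallel 0/1 matrix and defines observedness; a cell the
        mask marks observed must then hold a value.
        """
        values = _read_numeric_table(path, sep)
        if mask_path is None:
            return cls.from_values(values)
        mask = _read_numeric_table(mask_path, sep)
        if mask.shape != values.shape:
            raise ValueError(
                f"mask shape {mask.shape} does not match matrix shape {values.shape}"
            )
        observed = mask.astype(bool)
        if (observed & ~np.isfinite(values)).any():
            raise ValueError("mask marks a cell observed but the value is missing")
        return cls(values=values, observed=observed)

    def subset(self, rows: Sequence[int] | np.ndarray) -> "MaskedDataset":
        rows = np.asarray(rows, dtype=int)
        return MaskedDataset(values=self.values[rows], observed=self.observed[rows])


def _read_numeric_table(path: str | Path, sep: str | None) -> np.ndarray:
    """Read CSV/TSV into a float matrix, tolerating an optional header row
    and an optional leading row-id column."""
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, header=None, skipinitialspace=True)
    if df.empty:
        raise ValueError(f"{path}: empty table")

    def _numeric(frame: pd.DataFrame) -> pd.DataFrame | None:
        try:
            return frame.apply(pd.to_numeric, errors="raise")
        except (ValueError, TypeError):
            return None

    num = _numeric(df)
    if num is None:
        num = _numeric(df.iloc[1:])  # header row
        if num is None:
            num = _numeric(df.iloc[1:, 1:])  # header row + id column
            if num is None:
                num = _numeric(df.iloc[:, 1:])  # id column only
        if num is None:
            raise ValueError(f"{path}: could not interpret table as numeric")
    return num.to_numpy(dtype=float)


def zscore(data: MaskedDataset) -> MaskedDataset:
    """Column-wise standardization over observed cells (opt-in; clustering
    does not standardize by default)."""
    vals = np.array(data.values, copy=True)
    for d in range(data.d):
        col = vals[:, d]
        obs = data.observed[:, d]
        mu = col[obs].mean()
        sd = col[obs].std()
        col[obs] = (col[obs] - mu) / (sd if sd > 0 else 1.0)
    return MaskedDataset(values=vals, observed=data.observed)


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def partial_sq_distance(
    x: np.ndarray,
    y: np.ndarray,
    mask_x: np.ndarray | None = None,
    mask_y: np.ndarray | None = None,
) -> float:
    """Rescaled squared distance over the shared observed features.

    Returns ``(D / |O|) * sum_{d in O} (x_d - y_d)^2`` where ``O`` is the set
    of features observed in both rows; with all-True masks this is the
    ordinary squared Euclidean distance.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("vectors must have equal length")
    d = x.size
    mx = np.ones(d, dtype=bool) if mask_x is None else np.asarray(mask_x, dtype=bool)
    my = np.ones(d, dtype=bool) if mask_y is None else np.asarray(mask_y, dtype=bool)
    if mx.size != d or my.size != d:
        raise ValueError("masks must match vector length")
    overlap = mx & my
    n_shared = int(overlap.sum())
    if n_shared == 0:
        raise EmptyOverlapError("no shared observed features between the two rows")
    diff = x[overlap] - y[overlap]
    return float(d / n_shared * (diff @ diff))


def pairwise_partial_sq_distances(
    values_a: np.ndarray,
    observed_a: np.ndarray,
    values_b: np.ndarray | None = None,
    observed_b: np.ndarray | None = None,
    empty_overlap: str = "raise",
) -> np.ndarray:
    """All-pairs rescaled squared distances between the rows of A and B.

    Vectorized: with ``X0`` the matrix with unobserved cells zeroed and ``M``
    the 0/1 mask, the overlap sum of squared differences between rows is
    ``X0_a^2 M_b' + M_a X0_b^2' - 2 X0_a X0_b'`` and the overlap count is
    ``M_a M_b'``.

    ``empty_overlap`` controls pairs sharing no observed feature:
    ``"raise"`` (default) raises :class:`EmptyOverlapError` identifying the
    pair, ``"nan"`` leaves NaN in those cells for the caller to fill.
    """
    if empty_overlap not in ("raise", "nan"):
        raise ValueError("empty_overlap must be 'raise' or 'nan'")
    if values_b is None:
        values_b, observed_b = values_a, observed_a
    d = values_a.shape[1]
    a0 = np.where(observed_a, values_a, 0.0)
    b0 = np.where(observed_b, values_b, 0.0)
    ma = observed_a.astype(float)
    mb = observed_b.astype(float)
    sq = (a0**2) @ mb.T + ma @ (b0**2).T - 2.0 * (a0 @ b0.T)
    overlap = ma @ mb.T
    empty = overlap < 0.5
    if empty.any():
        if empty_overlap == "raise":
            i, j = np.argwhere(empty)[0]
            raise EmptyOverlapError(
                f"rows {int(i)} and {int(j)} share no observed features"
            )
        overlap[empty] = 1.0  # placeholder; cells overwritten below
    out = (d / overlap) * sq
    np.maximum(out, 0.0, out=out)  # clip round-off negatives
    if empty.any():
        out[empty] = np.nan
    return out


def column_variances(data: MaskedDataset) -> np.ndarray:
    """Per-feature variance over the observed entries (0 for features with
    fewer than two observations)."""
    out = np.zeros(data.d)
    for d in range(data.d):
        col = data.values[data.observed[:, d], d]
        if col.size >= 2:
            out[d] = float(col.var())
    return out


def penalized_sq_distances(
    data: MaskedDataset, rows: np.ndarray | None = None
) -> np.ndarray:
    """Variance-penalized squared distances used for similarity matrices.

    For a pair of rows the distance is the squared difference summed over
    the features observed in *both*, plus an uncertainty surcharge of one
    marginal feature variance for every feature a row is missing (a feature
    missing in both rows is charged twice).  With all-true masks this is the
    ordinary squared Euclidean distance.

    The surcharge is the key to clustering with incomplete rows: during
    assignment it is constant across candidate exemplars, so points are
    assigned by their observed coordinates alone, while an incomplete row
    is expensive for *everyone* to adopt as an exemplar — preventing a row
    that is blind to one dimension from spuriously representing (and
    merging) clusters separated along it.  Pairs with no shared observed
    feature are automatically mapped to a pure-surcharge distance, never
    silently to zero.

    ``rows`` selects candidate columns (all rows when ``None``); the
    surcharge uses dataset-level variances, so compressed entries equal the
    corresponding full-matrix entries exactly.
    """
    variances = column_variances(data)
    surcharge = ((~data.observed) * variances).sum(axis=1)
    a0 = np.where(data.observed, data.values, 0.0)
    ma = data.observed.astype(float)
    if rows is None:
        b0, mb, sb = a0, ma, surcharge
    else:
        b0, mb, sb = a0[rows], ma[rows], surcharge[rows]
    sq = (a0**2) @ mb.T + ma @ (b0**2).T - 2.0 * (a0 @ b0.T)
    np.maximum(sq, 0.0, out=sq)
    return sq + surcharge[:, None] + sb[None, :]


# ---------------------------------------------------------------------------
# Similarity matrices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimilarityMatrix:
    """Negative squared distances with a preference-bearing diagonal.

    Full form: a symmetric N x N matrix whose diagonal uniformly equals the
    preference.  Compressed form: an N x c matrix whose columns correspond to
    candidate exemplars; ``candidate_map[j]`` is the dataset row behind
    column ``j`` and entry ``(candidate_map[j], j)`` holds the preference.
    """

    values: np.ndarray
    preference: float
    candidate_map: np.ndarray
    is_compressed: bool = False
    _col_of: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        cmap = np.asarray(self.candidate_map, dtype=int)
        object.__setattr__(self, "candidate_map", cmap)
        if len(np.unique(cmap)) != cmap.size:
            raise ValueError("candidate_map contains duplicates")
        if self.values.shape[1] != cmap.size:
            raise ValueError("one column per candidate required")
        object.__setattr__(
            self, "_col_of", {int(r): j for j, r in enumerate(cmap)}
        )

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_candidates(self) -> int:
        return self.values.shape[1]

    def col(self, row: int) -> int:
        """Column index of a candidate dataset row."""
        try:
            return self._col_of[int(row)]
        except KeyError:
            raise KeyError(f"row {row} is not a candidate exemplar") from None

    def cols(self, rows: Sequence[int] | np.ndarray) -> np.ndarray:
        return np.array([self.col(r) for r in rows], dtype=int)

    def sim(self, i: int, row: int) -> float:
        """Similarity between point ``i`` and candidate dataset row ``row``."""
        return float(self.values[i, self.col(row)])


def median_preference(data: MaskedDataset) -> float:
    """Median similarity over the unordered off-diagonal pairs."""
    if data.n < 2:
        raise ValueError("preference needs at least two rows")
    d2 = penalized_sq_distances(data)
    iu = np.triu_indices(data.n, k=1)
    return float(np.median(-d2[iu]))


def build_similarity(
    data: MaskedDataset, preference: float | None = None
) -> SimilarityMatrix:
    """Full N x N similarity matrix; diagonal set to the preference
    (median of the off-diagonal similarities unless given)."""
    if data.n < 2:
        raise ValueError("similarity matrix needs at least two rows")
    d2 = penalized_sq_distances(data)
    s = -d2
    if preference is None:
        iu = np.triu_indices(data.n, k=1)
        preference = float(np.median(s[iu]))
    np.fill_diagonal(s, preference)
    return SimilarityMatrix(
        values=s,
        preference=float(preference),
        candidate_map=np.arange(data.n),
        is_compressed=False,
    )


def build_compressed_similarity(
    data: MaskedDataset,
    candidates,
    preference: float | None = None,
) -> SimilarityMatrix:
    """N x c similarity matrix against a candidate-exemplar list.

    Entries equal the corresponding full-matrix entries; the cell pairing a
    candidate with its own row carries the preference, which defaults to the
    median over the full dataset's off-diagonal pairs so that compression
    does not shift the model-selection pressure.
    """
    rows = np.asarray(getattr(candidates, "rows", candidates), dtype=int)
    if rows.size == 0:
        raise ValueError("candidate list is empty")
    if len(np.unique(rows)) != rows.size:
        raise ValueError("candidate list contains duplicates")
    if rows.min() < 0 or rows.max() >= data.n:
        raise ValueError("candidate index out of range")
    d2 = penalized_sq_distances(data, rows)
    s = -d2
    if preference is None:
        preference = median_preference(data)
    s[rows, np.arange(rows.size)] = preference
    return SimilarityMatrix(
        values=s,
        preference=float(preference),
        candidate_map=rows,
        is_compressed=True,
    )
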