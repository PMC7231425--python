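"""Seeded generators so every stage is testable without downloads.

Three generators are provided:

* :func:`make_clusters` — isotropic Gaussian blobs with rejection-sampled
  centres kept at least ``separation`` within-cluster standard deviations
  apart.  The default shape mirrors the planar seven-cluster benchmark this
  method is usually demonstrated on (788 points, 2 features, 7 clusters).
* :func:`inject_missing` — masks a fixed number of features in an exact
  fraction of randomly chosen rows (default: 20% of rows lose one
  feature), reproducing the random complete/incomplete split used in the
  evaluation protocol.  Observed values are never altered, only the mask.
* :func:`make_synthetic_eeg` — five groups of labelled EEG-like segments
  (two oscillation-only "healthy" groups, two oscillation-plus-spike
  "interictal" groups, one high-amplitude spike-wave "seizure" group) at
  173.6 Hz and 23.6 s by default.  Segments within a group share a phase
  reference with small jitter, which keeps raw-signal geometry
  cluster-friendly; see the package methods note for what this does and
  does not emulate.

An optional loader accepts a user-supplied copy of the published planar
benchmark in its two-columns-plus-label text format; it is not bundled.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .data import MaskedDataset
from .eeg import DEFAULT_FS, EEGSegment

__all__ = [
    "SyntheticSpec",
    "make_clusters",
    "inject_missing",
    "make_synthetic_eeg",
    "load_labelled_points",
    "write_dataset_csv",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Shape and noise parameters of a Gaussian-cluster scenario."""

    n_points: int = 788
    n_features: int = 2
    n_clusters: int = 7
    cluster_separation: float = 8.0  # in units of within-cluster sigma
    sigma: float = 1.0
    incomplete_fraction: float = 0.2
    k_missing: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.incomplete_fraction < 1.0):
            raise ValueError("incomplete_fraction must lie in [0, 1)")
        if self.k_missing >= self.n_features:
            raise ValueError("k_missing must leave at least one feature observed")
        if self.n_clusters > self.n_points:
            raise ValueError("more clusters than points")


def _sample_centers(
    rng: np.random.Generator,
    n_clusters: int,
    n_features: int,
    min_dist: float,
    budget: int = 5000,
) -> np.ndarray:
    """Rejection-sample cluster centres pairwise at least ``min_dist``
    apart inside a box scaled to make the packing feasible."""
    box = min_dist * (np.ceil(n_clusters ** (1.0 / n_features)) + 1.0)
    centers: list[np.ndarray] = []
    for _ in range(budget):
        cand = rng.uniform(0.0, box, size=n_features)
        if all(np.linalg.norm(cand - c) >= min_dist for c in centers):
            centers.append(cand)
            if len(centers) == n_clusters:
                return np.stack(centers)
    raise RuntimeError(
        f"could not place {n_clusters} centres at separation {min_dist} "
        f"within {budget} draws"
    )


def make_clusters(spec: SyntheticSpec) -> tuple[MaskedDataset, np.ndarray]:
    """Well-separated isotropic Gaussian clusters with near-equal sizes.

    Returns an all-observed dataset and integer class labels ``1..K``;
    identical seeds give identical output.
    """
    rng = np.random.default_rng(spec.seed)
    centers = _sample_centers(
        rng,
        spec.n_clusters,
        spec.n_features,
        spec.cluster_separation * spec.sigma,
    )
    base, extra = divmod(spec.n_points, spec.n_clusters)
    sizes = np.array(
        [base + (1 if k < extra else 0) for k in range(spec.n_clusters)]
    )
    values = np.vstack(
        [
            centers[k] + spec.sigma * rng.standard_normal((sizes[k], spec.n_features))
            for k in range(spec.n_clusters)
        ]
    )
    labels = np.repeat(np.arange(1, spec.n_clusters + 1), sizes)
    observed = np.ones_like(values, dtype=bool)
    return MaskedDataset(values=values, observed=observed), labels


def inject_missing(
    data: MaskedDataset,
    fraction: float,
    k_missing: int = 1,
    seed: int = 0,
) -> MaskedDataset:
    """Mask ``k_missing`` uniformly chosen features in exactly
    ``round(fraction * N)`` uniformly chosen rows.

    Only the mask changes; observed values are untouched.
    """
    if not (0.0 <= fraction < 1.0):
        raise ValueError("fraction must lie in [0, 1)")
    if k_missing >= data.d:
        raise ValueError("masking would leave a row with no observed features")
    rng = np.random.default_rng(seed)
    n_incomplete = int(round(fraction * data.n))
    observed = np.array(data.observed, copy=True)
    rows = rng.choice(data.n, size=n_incomplete, replace=False)
    for r in rows:
        feats = rng.choice(data.d, size=k_missing, replace=False)
        observed[r, feats] = False
        if not observed[r].any():
            raise ValueError(f"row {r} would lose all observed features")
    return MaskedDataset(values=data.values, observed=observed)


# group signatures: oscillation frequency (Hz), amplitude, noise sd,
# spike rate (Hz), spike amplitude
_EEG_GROUPS: dict[str, tuple[float, float, float, float, float]] = {
    "A": (10.0, 40.0, 8.0, 0.0, 0.0),  # healthy, eyes open
    "B": (10.0, 90.0, 8.0, 0.0, 0.0),  # healthy, eyes closed (stronger alpha)
    "C": (5.0, 55.0, 8.0, 1.0, 120.0),  # seizure-free interval, sparse spikes
    "D": (7.0, 25.0, 8.0, 3.0, 120.0),  # seizure-free interval, denser spikes
    "E": (3.0, 260.0, 15.0, 3.0, 400.0),  # seizure: spike-wave complexes
}


def make_synthetic_eeg(
    n_per_group: int = 100,
    fs: float = DEFAULT_FS,
    duration: float = 23.6,
    seed: int = 0,
) -> list[EEGSegment]:
    """Five groups (A–E) of labelled EEG-like segments.

    Each group has a distinct oscillation/spike/amplitude signature; within
    a group, segments share a phase reference with small jitter.  Returns
    ``5 * n_per_group`` segments ordered A..E.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be at least 1")
    rng = np.random.default_rng(seed)
    n_samples = int(round(fs * duration))
    t = np.arange(n_samples) / fs
    segments: list[EEGSegment] = []
    for group, (freq, amp, noise_sd, spike_rate, spike_amp) in _EEG_GROUPS.items():
        for _ in range(n_per_group):
            phase = rng.normal(0.0, 0.1)
            x = amp * np.sin(2.0 * np.pi * freq * t + phase)
            x = x + noise_sd * rng.standard_normal(n_samples)
            if spike_rate > 0:
                period = 1.0 / spike_rate
                spike_times = np.arange(0.5 * period, duration, period)
                spike_times = spike_times + rng.normal(0.0, 0.01, spike_times.size)
                for ts in spike_times:
                    x += spike_amp * np.exp(-0.5 * ((t - ts) / 0.02) ** 2)
            segments.append(EEGSegment(samples=x, fs=fs, group_label=group))
    return segments


def load_labelled_points(path: str | Path) -> tuple[MaskedDataset, np.ndarray]:
    """Load a user-supplied planar benchmark file: whitespace- or
    comma-separated columns ``x y label``."""
    values = []
    labels = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        parts = line.replace(",", " ").split()
        *feats, lab = parts
        values.append([float(v) for v in feats])
        labels.append(int(float(lab)))
    arr = np.array(values)
    data = MaskedDataset(values=arr, observed=np.ones_like(arr, dtype=bool))
    return data, np.array(labels)


def write_dataset_csv(
    data: MaskedDataset,
    out_dir: str | Path,
    labels: np.ndarray | None = None,
) -> dict[str, Path]:
    """Write ``features.csv`` (NaN for missing), ``mask.csv`` (0/1) and,
    when labels are given, ``labels.tsv``.  Returns the paths written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    feat = out_dir / "features.csv"
    with feat.open("w", newline="") as fh:
        writer = csv.writer(fh)
        for i in range(data.n):
            writer.writerow(
                [
                    repr(float(data.values[i, j])) if data.observed[i, j] else ""
                    for j in range(data.d)
                ]
            )
    paths["features"] = feat

    mask = out_dir / "mask.csv"
    with mask.open("w", newline="") as fh:
        writer = csv.writer(fh)
        for i in range(data.n):
            writer.writerow([int(v) for v in data.observed[i]])
    paths["mask"] = mask

    if labels is not None:
        lab = out_dir / "labels.tsv"
        lab.write_text("\n".join(str(int(l)) for l in labels) + "\n")
        paths["labels"] = lab
    return paths
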