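"""Kernel-PCA front end for raw single-channel EEG segments.

Segments arrive as plain ASCII files (one sample value per line), the
distribution format of the classic five-group scalp/intracranial EEG
archive: 100 segments per group, 23.6 s at 173.6 Hz (4097 samples).  Each
whole segment becomes one observation; kernel PCA with an RBF kernel
projects the segments to a small fixed-width feature vector (6 components
by default) that the clustering stage consumes.

The kernel width defaults to the median pairwise squared distance between
segments (the median heuristic).  Component signs are fixed by making each
component's largest-magnitude dual loading positive, so repeated runs are
bit-identical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist
from sklearn.decomposition import KernelPCA

from .data import MaskedDataset

__all__ = [
    "EEGSegment",
    "load_segment_ascii",
    "load_group_directory",
    "kpca_features",
]

DEFAULT_FS = 173.6  # Hz


@dataclass(frozen=True)
class EEGSegment:
    """A single-channel EEG segment (samples in microvolts)."""

    samples: np.ndarray
    fs: float = DEFAULT_FS
    group_label: str | None = None

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float).ravel()
        if samples.size == 0:
            raise ValueError("segment has no samples")
        if not np.isfinite(samples).all():
            raise ValueError("segment contains non-finite samples")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        samples.setflags(write=False)
        object.__setattr__(self, "samples", samples)

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return self.samples.size / self.fs


def load_segment_ascii(
    path: str | Path,
    fs: float = DEFAULT_FS,
    group_label: str | None = None,
) -> EEGSegment:
    """Read a one-sample-per-line ASCII segment file.

    Raises on empty files and on non-numeric lines (reporting the line
    number); attaches a warning when the trace has zero variance.
    """
    path = Path(path)
    values: list[float] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                values.append(float(line))
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric sample on line {lineno}: {line!r}"
                ) from None
    if not values:
        raise ValueError(f"{path}: empty segment file")
    samples = np.array(values)
    if samples.std() == 0:
        warnings.warn(
            f"{path}: zero-variance segment", UserWarning, stacklevel=2
        )
    return EEGSegment(samples=samples, fs=fs, group_label=group_label)


def load_group_directory(
    root: str | Path, fs: float = DEFAULT_FS
) -> list[EEGSegment]:
    """Load one subdirectory per group (e.g. A–E) of ASCII segment files;
    the subdirectory name becomes the group label."""
    root = Path(root)
    segments: list[EEGSegment] = []
    for sub in sorted(p for p in root.iterdir() if p.is_dir()):
        for f in sorted(sub.iterdir()):
            if f.is_file():
                segments.append(load_segment_ascii(f, fs=fs, group_label=sub.name))
    if not segments:
        raise ValueError(f"{root}: no segment files found")
    return segments


def kpca_features(
    segments: Sequence[EEGSegment],
    n_components: int = 6,
    kernel_width: float | None = None,
    kernel: str = "rbf",
    seed: int | None = None,
) -> tuple[MaskedDataset, np.ndarray | None]:
    """Project whole segments to ``n_components`` kernel-PCA scores.

    Segments are truncated to the shortest common length.  For the RBF
    kernel ``k(x, y) = exp(-||x - y||^2 / w)`` the width ``w`` defaults to
    the median pairwise squared distance.  Returns the feature matrix as an
    all-observed :class:`MaskedDataset` together with the group labels
    (``None`` when any segment is unlabelled).
    """
    if len(segments) < 2:
        raise ValueError("need at least two segments")
    if n_components >= len(segments):
        raise ValueError(
            f"n_components={n_components} must be smaller than the number of "
            f"segments ({len(segments)})"
        )
    min_len = min(seg.n_samples for seg in segments)
    x = np.stack([seg.samples[:min_len] for seg in segments])

    if kernel == "rbf":
        if kernel_width is None:
            kernel_width = float(np.median(pdist(x, metric="sqeuclidean")))
        if kernel_width <= 0:
            raise ValueError("kernel width must be positive")
        model = KernelPCA(
            n_components=n_components,
            kernel="rbf",
            gamma=1.0 / kernel_width,
            random_state=seed,
        )
    else:
        model = KernelPCA(n_components=n_components, kernel=kernel, random_state=seed)
    scores = model.fit_transform(x)

    # deterministic signs: largest-magnitude dual loading positive
    alphas = model.eigenvectors_
    for j in range(scores.shape[1]):
        i_star = int(np.abs(alphas[:, j]).argmax())
        if alphas[i_star, j] < 0:
            scores[:, j] = -scores[:, j]

    labels_list = [seg.group_label for seg in segments]
    labels = None if any(l is None for l in labels_list) else np.array(labels_list)
    dataset = MaskedDataset(values=scores, observed=np.ones_like(scores, dtype=bool))
    return dataset, labels
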