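"""Hybrid Nx2 spectra, labeled train/val/test datasets, and PCA diagnostics.

The classifier input stacks the absorption rate (column 0) and refractive
index (column 1) on the 240-point band into an Nx2 matrix.  Because the two
metrics live on incompatible scales (1/mm vs a dimensionless index near
1.7), each column is standardized with statistics computed on the training
split only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
from sklearn.decomposition import PCA

__all__ = [
    "HybridSpectrum",
    "Record",
    "LabeledDataset",
    "ColumnStats",
    "hybrid_spectrum",
    "assemble_datasets",
    "first_principal_component",
    "principal_scores",
]

_INPUT_MODES = {"hybrid": (0, 1), "absorption": (0,), "refractive": (1,)}


class Record(NamedTuple):
    """One extracted record: class label, tablet id, and band arrays."""

    label: str
    tablet_id: int
    alpha: np.ndarray
    n: np.ndarray


class ColumnStats(NamedTuple):
    mean: np.ndarray  # one value per column
    std: np.ndarray


@dataclass
class HybridSpectrum:
    """Nx2 stack of (absorption rate, refractive index) on the band grid."""

    matrix: np.ndarray
    f: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("hybrid spectrum must be 2-D (N x columns)")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("hybrid spectrum contains non-finite entries")


def hybrid_spectrum(
    alpha_band: np.ndarray,
    n_band: np.ndarray,
    standardize: bool = False,
    column_stats: ColumnStats | None = None,
    f: np.ndarray | None = None,
) -> HybridSpectrum:
    """Column-stack absorption rate and refractive index, column order (alpha, n).

    With ``standardize=True`` the columns are centered and scaled by
    ``column_stats`` — the training-set statistics supplied by the dataset
    assembler.
    """
    alpha_band = np.asarray(alpha_band, dtype=float)
    n_band = np.asarray(n_band, dtype=float)
    if alpha_band.shape != n_band.shape or alpha_band.ndim != 1:
        raise ValueError("alpha and n bands must be 1-D and equal length")
    matrix = np.column_stack([alpha_band, n_band])
    if standardize:
        if column_stats is None:
            raise ValueError("standardize=True requires column_stats")
        matrix = (matrix - column_stats.mean) / column_stats.std
    return HybridSpectrum(matrix=matrix, f=f)


@dataclass
class LabeledDataset:
    """Stacked spectra (n_items x N x n_columns) with integer class labels."""

    X: np.ndarray
    y: np.ndarray
    class_names: list[str]
    split_tag: str
    seed: int

    def __post_init__(self) -> None:
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y lengths differ")
        if self.X.shape[0] == 0:
            raise ValueError("dataset must be non-empty")
        if np.any(self.y < 0) or np.any(self.y >= len(self.class_names)):
            raise ValueError("class index out of range")

    def __len__(self) -> int:
        return self.X.shape[0]


def _stack(records: Sequence[Record]) -> np.ndarray:
    return np.stack([np.column_stack([r.alpha, r.n]) for r in records])


def assemble_datasets(
    records: Mapping[int, Sequence[Record]],
    input_mode: str = "hybrid",
    val_frac: float = 0.2,
    seed: int = 0,
    train_avg: int = 100,
    test_avgs: Sequence[int] = (20, 10),
    class_names: Sequence[str] | None = None,
) -> tuple[LabeledDataset, ...]:
    """Deterministic stratified split of the high-average group into train/val,
    with the noisier average groups as held-out test sets.

    Standardization statistics are computed from the training split only and
    applied to every split.  ``input_mode`` selects columns — 'hybrid' keeps
    (alpha, n), 'absorption'/'refractive' keep one column — enabling the
    single-metric ablations.
    """
    if input_mode not in _INPUT_MODES:
        raise ValueError(f"unknown input_mode {input_mode!r}")
    if train_avg not in records:
        raise ValueError(f"missing avg-{train_avg} group for train/val")
    for avg in test_avgs:
        if avg not in records:
            raise ValueError(f"missing avg-{avg} test group")

    if class_names is None:
        class_names = sorted({r.label for r in records[train_avg]})
    class_names = list(class_names)
    index = {name: i for i, name in enumerate(class_names)}

    rng = np.random.default_rng(seed)
    train_recs: list[Record] = []
    val_recs: list[Record] = []
    for name in class_names:
        group = [r for r in records[train_avg] if r.label == name]
        order = rng.permutation(len(group))
        n_val = int(round(val_frac * len(group)))
        val_recs.extend(group[i] for i in order[:n_val])
        train_recs.extend(group[i] for i in order[n_val:])

    cols = _INPUT_MODES[input_mode]
    x_train = _stack(train_recs)
    stats = ColumnStats(
        mean=x_train.reshape(-1, 2).mean(axis=0),
        std=x_train.reshape(-1, 2).std(axis=0),
    )
    if np.any(stats.std == 0):
        raise ValueError("degenerate training column (zero variance)")

    def finish(recs: Sequence[Record], tag: str) -> LabeledDataset:
        x = (_stack(recs) - stats.mean) / stats.std
        y = np.array([index[r.label] for r in recs], dtype=int)
        return LabeledDataset(
            X=x[:, :, cols], y=y, class_names=class_names, split_tag=tag, seed=seed
        )

    out = [finish(train_recs, "train"), finish(val_recs, "val")]
    for avg in test_avgs:
        out.append(finish(records[avg], f"test{avg}"))
    return tuple(out)


def _flatten_items(spectra) -> np.ndarray:
    rows = []
    for item in spectra:
        m = item.matrix if isinstance(item, HybridSpectrum) else np.asarray(item, float)
        rows.append(m.ravel(order="C"))
    x = np.asarray(rows)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 items for PCA")
    return x


def principal_scores(spectra, n_components: int = 2) -> np.ndarray:
    """Mean-centered PCA scores; each component's sign is fixed by making its
    largest-magnitude loading positive."""
    x = _flatten_items(spectra)
    if np.allclose(x, x[0]):
        raise ValueError("rank-0 data: all items identical")
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(x)
    for i, vec in enumerate(pca.components_):
        if vec[np.argmax(np.abs(vec))] < 0:
            scores[:, i] *= -1.0
    return scores


def first_principal_component(spectra) -> np.ndarray:
    """Projection of flattened, mean-centered items on the leading eigenvector."""
    return principal_scores(spectra, n_components=1)[:, 0]
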