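"""Functional network construction from epochs.

An epoch's connectivity matrix is the pairwise Pearson correlation of its
channels.  Networks are obtained by sparsity thresholding: the strongest
``round(density * N(N-1)/2)`` edges by absolute correlation are retained,
so every subject's network has the same edge count and topology
comparisons are unbiased with respect to density.  Negative correlations
enter through their magnitude (standard practice in EEG correlation
networks and required for the nonnegative-weight metric definitions).

``PearsonConnectivity`` and ``SparsityThreshold`` are stateless
scikit-learn transformers over batches of epochs / matrices;
:func:`pearson_matrix` and :func:`sparsity_threshold` are single-item
convenience wrappers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .preprocessing import Epoch

__all__ = [
    "ConnectivityMatrix",
    "Network",
    "PearsonConnectivity",
    "SparsityThreshold",
    "pearson_matrix",
    "sparsity_threshold",
]


@dataclass
class ConnectivityMatrix:
    """Symmetric Pearson correlation matrix with unit diagonal."""

    r: np.ndarray
    channel_labels: tuple[str, ...] = ()
    subject_id: str = ""
    group: str = ""
    state: str = ""
    epoch_index: int = 0

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        n = self.r.shape[0]
        if self.r.shape != (n, n):
            raise ValueError("correlation matrix must be square")
        if not np.allclose(self.r, self.r.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if np.any(np.abs(self.r) > 1 + 1e-12):
            raise ValueError("correlation entries must have magnitude <= 1")

    @property
    def n_nodes(self) -> int:
        return self.r.shape[0]


@dataclass
class Network:
    """Thresholded adjacency at fixed edge density (no self-loops).

    ``w`` holds |r| values in weighted mode or 0/1 in binary mode.
    """

    w: np.ndarray
    density: float
    mode: str
    channel_labels: tuple[str, ...] = ()
    subject_id: str = ""
    group: str = ""
    state: str = ""
    epoch_index: int = 0

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if self.mode not in ("weighted", "binary"):
            raise ValueError("mode must be 'weighted' or 'binary'")
        if not np.allclose(self.w, self.w.T, atol=1e-12):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(self.w) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if np.any(self.w < 0):
            raise ValueError("edge weights must be nonnegative")

    @property
    def n_nodes(self) -> int:
        return self.w.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.w, 1)))

    def binary_pattern(self) -> np.ndarray:
        """0/1 adjacency pattern (identical to ``w`` in binary mode)."""
        return (self.w > 0).astype(float)

    def degrees(self) -> np.ndarray:
        return self.binary_pattern().sum(axis=1)

    def edge_list(self) -> list[tuple[int, int, float]]:
        ii, jj = np.nonzero(np.triu(self.w, 1))
        return [(int(i), int(j), float(self.w[i, j])) for i, j in zip(ii, jj)]

    def to_csv(self, path, edges: bool = False) -> None:
        """Write the adjacency as a labelled square CSV, or as an
        (i, j, weight) edge list with ``edges=True``."""
        import pandas as pd

        labels = list(self.channel_labels) or [
            f"CH{i + 1}" for i in range(self.n_nodes)
        ]
        if edges:
            pd.DataFrame(
                [(labels[i], labels[j], w) for i, j, w in self.edge_list()],
                columns=["i", "j", "weight"],
            ).to_csv(path, index=False)
        else:
            pd.DataFrame(self.w, index=labels, columns=labels).to_csv(path)


class PearsonConnectivity(TransformerMixin, BaseEstimator):
    """Map epochs to Pearson connectivity matrices.

    Stateless transformer: ``fit`` only validates. ``transform`` accepts a
    list of :class:`Epoch` (or a 3-D array epochs x channels x samples) and
    returns a list of :class:`ConnectivityMatrix`.
    """

    def fit(self, X, y=None):
        self.n_features_in_ = len(X)
        return self

    def transform(self, X):
        return [self._one(e) for e in X]

    @staticmethod
    def _one(epoch) -> ConnectivityMatrix:
        if isinstance(epoch, Epoch):
            data, labels = epoch.data, epoch.channel_labels
            tags = dict(
                subject_id=epoch.subject_id,
                group=epoch.group,
                state=epoch.state,
                epoch_index=epoch.epoch_index,
            )
        else:
            data = np.asarray(epoch, dtype=float)
            labels = tuple(f"CH{i + 1}" for i in range(data.shape[0]))
            tags = {}
        if data.shape[1] < 2:
            raise ValueError("need at least 2 samples per channel")
        sd = data.std(axis=1)
        dead = np.flatnonzero(sd == 0)
        if dead.size:
            names = ", ".join(labels[i] for i in dead)
            raise FloatingPointError(
                f"zero-variance channel(s) {names}: correlation undefined"
            )
        r = np.corrcoef(data)
        np.fill_diagonal(r, 1.0)
        r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
        return ConnectivityMatrix(r=r, channel_labels=tuple(labels), **tags)


class SparsityThreshold(TransformerMixin, BaseEstimator):
    """Fixed-density thresholding of connectivity matrices.

    Parameters
    ----------
    density : float in (0, 1]
        Fraction of the N(N-1)/2 possible edges to retain; realized to the
        nearest whole edge count.
    mode : {"weighted", "binary"}
        Retained edges carry |r| (weighted) or 1 (binary).

    Ranking is by |r| descending; ties crossing the cutoff are broken by
    lexicographic (i, j) order, making the edge set deterministic and
    nested across densities.
    """

    def __init__(self, density: float = 0.3, mode: str = "weighted"):
        self.density = density
        self.mode = mode

    def fit(self, X, y=None):
        if not 0 < self.density <= 1:
            raise ValueError("density must lie in (0, 1]")
        if self.mode not in ("weighted", "binary"):
            raise ValueError("mode must be 'weighted' or 'binary'")
        self.n_features_in_ = len(X)
        return self

    def transform(self, X):
        self.fit(X)
        return [self._one(cm) for cm in X]

    def _one(self, cm: ConnectivityMatrix) -> Network:
        if not isinstance(cm, ConnectivityMatrix):
            cm = ConnectivityMatrix(r=np.asarray(cm, dtype=float))
        n = cm.n_nodes
        n_possible = n * (n - 1) // 2
        k = int(round(self.density * n_possible))
        if k < 1:
            raise ValueError(
                f"density {self.density} retains zero of {n_possible} edges"
            )
        iu, ju = np.triu_indices(n, 1)
        mag = np.abs(cm.r[iu, ju])
        # sort by (-|r|, i, j): descending magnitude, lexicographic tie-break
        order = np.lexsort((ju, iu, -mag))
        keep = order[:k]
        w = np.zeros((n, n))
        vals = np.ones(k) if self.mode == "binary" else mag[keep]
        w[iu[keep], ju[keep]] = vals
        w[ju[keep], iu[keep]] = vals
        return Network(
            w=w,
            density=self.density,
            mode=self.mode,
            channel_labels=cm.channel_labels,
            subject_id=cm.subject_id,
            group=cm.group,
            state=cm.state,
            epoch_index=cm.epoch_index,
        )


def pearson_matrix(epoch) -> ConnectivityMatrix:
    """Pearson correlation matrix of one epoch (channels x samples)."""
    return PearsonConnectivity._one(epoch)


def sparsity_threshold(
    cm, density: float = 0.3, mode: str = "weighted"
) -> Network:
    """Threshold one connectivity matrix to a fixed-density network."""
    st = SparsityThreshold(density=density, mode=mode)
    st.fit([cm])
    return st._one(cm)
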