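"""Per-subject feature vectors from epoch-level graph metrics.

The layout follows the 7 measures x N electrodes x n_epochs design
(504 features under the defaults of 8 electrodes and 9 epochs): for each
epoch, the per-node values of the seven measures are concatenated in the
fixed order of :data:`eeggraph.metrics.METRIC_NAMES`.  Three measures are
network-level; their slots are filled with their nodal counterparts
(nodal efficiency for the global-efficiency slot, nodal mean distance for
the path-length slot) and network assortativity broadcast to all nodes.
A NaN assortativity (degree-regular network) is imputed as 0 with a
warning.  A network-scalar-broadcast alternative is available via
``nodal=False``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .metrics import METRIC_NAMES, MetricSet

__all__ = ["FeatureVector", "build_features", "feature_table"]

N_METRICS = len(METRIC_NAMES)


@dataclass
class FeatureVector:
    """Layout-ordered features for one subject/state."""

    values: np.ndarray
    layout: list[tuple[str, str, int]]  # (metric, node, epoch)
    subject_id: str
    group: str
    state: str

    def __len__(self) -> int:
        return len(self.values)


def _epoch_block(ms: MetricSet, nodal: bool) -> np.ndarray:
    if nodal:
        block = ms.nodal_matrix()
    else:
        n = ms.n_nodes
        scalars = ms.network_scalars()
        block = np.vstack([np.full(n, scalars[name]) for name in METRIC_NAMES])
    if np.isnan(block).any():
        warnings.warn(
            f"NaN assortativity imputed as 0 for subject "
            f"{ms.subject_id!r} state {ms.state!r} epoch {ms.epoch_index}",
            stacklevel=3,
        )
        block = np.nan_to_num(block, nan=0.0)
    return block


def build_features(
    metrics: list[MetricSet], n_epochs: int | None = None, nodal: bool = True
) -> FeatureVector:
    """Assemble one subject/state feature vector from its epoch metrics.

    Parameters
    ----------
    metrics : list of MetricSet
        Exactly ``n_epochs`` epoch-level metric sets, consistent N.
    n_epochs : int, optional
        Expected epoch count; defaults to ``len(metrics)``.
    nodal : bool
        Use nodal stand-ins for the three network-level measures (default)
        rather than broadcasting the network scalars.

    Returns a vector of length ``7 * N * n_epochs``.
    """
    if n_epochs is None:
        n_epochs = len(metrics)
    if len(metrics) != n_epochs:
        raise ValueError(
            f"expected {n_epochs} epoch metric sets, got {len(metrics)}"
        )
    if not metrics:
        raise ValueError("need at least one epoch")
    n = metrics[0].n_nodes
    if any(ms.n_nodes != n for ms in metrics):
        raise ValueError("inconsistent node count across epochs")
    labels = metrics[0].channel_labels or tuple(f"CH{i + 1}" for i in range(n))

    blocks, layout = [], []
    for ms in sorted(metrics, key=lambda m: m.epoch_index):
        blocks.append(_epoch_block(ms, nodal).ravel())
        for metric in METRIC_NAMES:
            for node in labels:
                layout.append((metric, node, ms.epoch_index))
    first = metrics[0]
    return FeatureVector(
        values=np.concatenate(blocks),
        layout=layout,
        subject_id=first.subject_id,
        group=first.group,
        state=first.state,
    )


def feature_table(
    metric_sets: list[MetricSet],
    per_epoch: bool = False,
    nodal: bool = True,
) -> pd.DataFrame:
    """Feature matrix over a cohort, one row per instance.

    ``per_epoch=False`` (default): one row per (subject, state) holding the
    full 7 x N x n_epochs vector.  ``per_epoch=True``: one row per
    (subject, state, epoch) holding a 7 x N vector — the instance layout
    that matches epoch-level classification.  Feature columns are named
    ``{metric}|{node}|e{epoch}`` (or ``{metric}|{node}`` per-epoch), with
    ``group`` and ``state`` metadata columns first.
    """
    groups: dict[tuple[str, str], list[MetricSet]] = {}
    for ms in metric_sets:
        groups.setdefault((ms.subject_id, ms.state), []).append(ms)

    rows = []
    for (sid, state), mss in sorted(groups.items()):
        mss = sorted(mss, key=lambda m: m.epoch_index)
        if per_epoch:
            for ms in mss:
                fv = build_features([ms], nodal=nodal)
                row = {"subject_id": sid, "group": ms.group, "state": state,
                       "epoch": ms.epoch_index}
                row.update(
                    {f"{m}|{nd}": v for (m, nd, _), v in zip(fv.layout, fv.values)}
                )
                rows.append(row)
        else:
            fv = build_features(mss, nodal=nodal)
            row = {"subject_id": sid, "group": fv.group, "state": state}
            row.update(
                {f"{m}|{nd}|e{e}": v for (m, nd, e), v in zip(fv.layout, fv.values)}
            )
            rows.append(row)
    return pd.DataFrame(rows)
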