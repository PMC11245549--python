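"""Winner-take-all network parcellation of the subcortex.

Each subcortical voxel is assigned to the cortical network that accounts
for the largest share of its top-K most strongly connected cortical ROIs
(K = 100 by default); the share itself is the parcellation confidence.
Ranking uses the unsparsified FC row — any strictly monotone transform of
the row (r vs Fisher z) leaves the assignment unchanged.  Ties in FC
values are broken by ROI index and ties in network counts by the lower
network id, so the procedure is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from subgrad.connectivity import FCMatrix

N_NETWORKS = 7


@dataclass
class NetworkParcellation:
    """Per-voxel network labels (1..7) and confidence n_winner / k."""

    labels: np.ndarray
    confidence: np.ndarray
    k: int


class TopKNetworkParcellation(BaseEstimator):
    """Top-K winner-take-all assignment of voxels to cortical networks."""

    def __init__(self, k: int = 100, n_networks: int = N_NETWORKS):
        self.k = k
        self.n_networks = n_networks

    def fit(self, fc: FCMatrix | np.ndarray, cortical_labels: np.ndarray):
        values = fc.values if isinstance(fc, FCMatrix) else np.asarray(fc, float)
        cortical_labels = np.asarray(cortical_labels, dtype=int)
        n_vox, n_roi = values.shape
        if self.k > n_roi:
            raise ValueError(f"k={self.k} exceeds ROI count {n_roi}")
        if cortical_labels.shape[0] != n_roi:
            raise ValueError("one network label per cortical ROI required")
        if cortical_labels.min() < 1 or cortical_labels.max() > self.n_networks:
            raise ValueError(f"network labels must lie in 1..{self.n_networks}")

        # descending by FC value, FC ties broken by lowest ROI index
        order = np.argsort(-values, axis=1, kind="stable")[:, : self.k]
        top_labels = cortical_labels[order]                      # (n_vox, k)
        counts = np.stack(
            [(top_labels == net).sum(axis=1) for net in range(1, self.n_networks + 1)],
            axis=1,
        )
        # argmax returns the first (lowest-id) maximum: documented tie rule
        winner = counts.argmax(axis=1)
        self.labels_ = winner + 1
        self.confidence_ = counts[np.arange(n_vox), winner] / self.k
        return self

    def fit_predict(self, fc, cortical_labels) -> NetworkParcellation:
        self.fit(fc, cortical_labels)
        return NetworkParcellation(
            labels=self.labels_, confidence=self.confidence_, k=self.k
        )


def assign_networks_topk(
    fc: FCMatrix, cortical_labels: np.ndarray, k: int = 100
) -> NetworkParcellation:
    """Functional wrapper over :class:`TopKNetworkParcellation`."""
    return TopKNetworkParcellation(k=k).fit_predict(fc, cortical_labels)


def network_summary(
    voxel_map: np.ndarray,
    parc: NetworkParcellation | np.ndarray,
    stat: str = "mean",
    n_networks: int = N_NETWORKS,
) -> np.ndarray:
    """Summarize a voxelwise map per network: ``mean`` or ``sum_abs``.

    Empty networks yield NaN (flagged undefined rather than an error so a
    partial parcellation still summarizes).
    """
    labels = parc.labels if isinstance(parc, NetworkParcellation) else np.asarray(parc)
    voxel_map = np.asarray(voxel_map, dtype=float)
    if voxel_map.shape[0] != labels.shape[0]:
        raise ValueError("map and parcellation must share the voxel count")
    if stat not in ("mean", "sum_abs"):
        raise ValueError("stat must be 'mean' or 'sum_abs'")
    out = np.full(n_networks, np.nan)
    for net in range(1, n_networks + 1):
        sel = labels == net
        if not sel.any():
            continue
        if stat == "mean":
            out[net - 1] = voxel_map[sel].mean()
        else:
            out[net - 1] = np.abs(voxel_map[sel]).sum()
    return out
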