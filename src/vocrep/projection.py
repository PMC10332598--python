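"""Dimensionality reduction (UMAP) and density clustering (HDBSCAN).

Bottleneck embeddings are projected with UMAP — 8 dimensions for
clustering, 2 for visualisation — then grouped with HDBSCAN.  The generic
clustering settings that transfer well across repertoires are a minimum
cluster size of 10, minimum samples of 3, a cluster-selection epsilon of
0.1 and the *leaf* selection strategy (*eom* is selectable; it helps on
graded repertoires where leaves over-fragment).  Points in no dense region
receive the ``NOISE`` sentinel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import HDBSCAN

__all__ = ["NOISE", "ClusterParams", "ClusterAssignment", "project", "cluster"]

#: Label given to vocalisations that fall in no dense region.
NOISE = -1


def project(
    embeddings: np.ndarray,
    n_dims: int = 8,
    seed: int = 0,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
) -> np.ndarray:
    """UMAP projection of ``(n, d)`` embeddings to ``(n, n_dims)``.

    Neighbourhood size and minimum distance stay at the reference
    implementation's defaults; only the output dimensionality is treated as
    a setting (8 for clustering, 2 for plots).  The seed is mandatory state:
    UMAP is stochastic and every downstream artifact records it.
    """
    import umap  # deferred: slow import (numba compilation)

    embeddings = np.asarray(embeddings, dtype=float)
    if not np.isfinite(embeddings).all():
        raise ValueError("embeddings contain non-finite values")
    if len(embeddings) <= n_neighbors:
        raise ValueError(
            f"only {len(embeddings)} points for n_neighbors={n_neighbors}; "
            "reduce n_neighbors or provide more data"
        )
    reducer = umap.UMAP(n_components=n_dims, n_neighbors=n_neighbors,
                        min_dist=min_dist, random_state=seed)
    with warnings.catch_warnings():
        # umap warns that a fixed random_state disables parallelism; that
        # determinism is exactly what we ask for
        warnings.filterwarnings("ignore", module="umap")
        warnings.filterwarnings("ignore", message=".*n_jobs value.*random_state.*")
        return np.asarray(reducer.fit_transform(embeddings), dtype=float)


@dataclass
class ClusterParams:
    """HDBSCAN settings; defaults are the generic cross-repertoire choice."""

    min_cluster_size: int = 10
    min_samples: int = 3
    epsilon: float = 0.1
    selection: str = "leaf"

    def __post_init__(self) -> None:
        if self.selection not in ("leaf", "eom"):
            raise ValueError(f"selection must be 'leaf' or 'eom', got {self.selection!r}")


@dataclass
class ClusterAssignment:
    """Cluster id per vocalisation (``NOISE`` = -1), plus the settings used."""

    labels: np.ndarray
    params: ClusterParams = field(default_factory=ClusterParams)

    @property
    def n_clusters(self) -> int:
        return int(len(set(self.labels[self.labels != NOISE])))

    @property
    def n_noise(self) -> int:
        return int((self.labels == NOISE).sum())


def cluster(embeddings: np.ndarray, params: ClusterParams | None = None) -> ClusterAssignment:
    """HDBSCAN density clustering of projected embeddings.

    Cluster ids are contiguous from 0; unassigned points get ``NOISE``.
    With fewer points than ``min_cluster_size`` no dense region can exist:
    everything is NOISE (with a warning) rather than an error, since sparse
    inputs are a legitimate edge of exploratory runs.
    """
    params = params or ClusterParams()
    embeddings = np.asarray(embeddings, dtype=float)
    n = len(embeddings)
    if n < params.min_cluster_size:
        warnings.warn(
            f"{n} points < min_cluster_size={params.min_cluster_size}: all noise",
            stacklevel=2,
        )
        return ClusterAssignment(np.full(n, NOISE), params)
    model = HDBSCAN(
        min_cluster_size=params.min_cluster_size,
        min_samples=params.min_samples,
        cluster_selection_epsilon=params.epsilon,
        cluster_selection_method=params.selection,
        copy=True,
    )
    raw = model.fit_predict(embeddings)
    labels = np.full(n, NOISE)
    for new_id, old in enumerate(sorted(set(raw[raw >= 0]))):
        labels[raw == old] = new_id
    return ClusterAssignment(labels, params)
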