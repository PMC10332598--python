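"""Agreement, clusterability and annotation-effort metrics.

Three questions are answered about a clustering of a repertoire:

* **Agreement with expert labels** — normalised mutual information between
  the cluster partition and the expert type labels,

  ``NMI(L; C) = D_KL(P_LC || P_L (x) P_C) * 2 / (H(L) + H(C))``,

  i.e. mutual information normalised by the arithmetic mean of the two
  entropies; 1 for a perfect match, 0 for unrelated partitions.

* **Clusterability** — the Hopkins statistic, comparing nearest-neighbour
  distances of points drawn from a moment-matched normal distribution
  against those of the data itself: ~0.5 for unstructured data, toward 1
  for a discrete (clusterable) repertoire.

* **Annotation effort** — the discriminant-cluster report: a cluster is
  *discriminant* when at least 90% of its labelled members share one type,
  so its whole content can be bulk-annotated; the report counts clusters,
  the proportion that are discriminant, the proportion of vocalisations
  they hold, and the labels that are missed entirely.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .projection import NOISE

__all__ = [
    "nmi",
    "hopkins",
    "AnnotationReport",
    "discriminant_report",
    "filter_rare_labels",
]


def _is_labelled(labels: np.ndarray) -> np.ndarray:
    return ~pd.isna(pd.Series(labels)).to_numpy()


def nmi(labels, clusters, noise_policy: str = "exclude") -> float:
    """Normalised mutual information between expert labels and clusters.

    Computed over vocalisations that are both labelled (non-null label) and
    clustered.  ``noise_policy="exclude"`` drops NOISE-assigned points from
    the contingency table; ``"singletons"`` keeps them, each as its own
    cluster.  Entropies are in natural log (the base cancels).  If both
    partitions are single-category the ratio is 0/0; a perfect match is
    returned (1.0) with a warning.
    """
    labels = np.asarray(labels, dtype=object)
    clusters = np.asarray(clusters)
    if labels.shape != clusters.shape:
        raise ValueError("labels and clusters must align")
    keep = _is_labelled(labels)
    if noise_policy == "exclude":
        keep &= clusters != NOISE
        clusters_eff = clusters
    elif noise_policy == "singletons":
        clusters_eff = clusters.copy()
        fresh = clusters.max(initial=0) + 1
        for i in np.flatnonzero(clusters == NOISE):
            clusters_eff[i] = fresh
            fresh += 1
    else:
        raise ValueError(f"unknown noise_policy {noise_policy!r}")
    if not keep.any():
        raise ValueError("no vocalisation is both labelled and clustered")

    table = pd.crosstab(pd.Series(labels[keep]), pd.Series(clusters_eff[keep]))
    joint = table.to_numpy(dtype=float)
    joint /= joint.sum()
    p_l = joint.sum(axis=1)
    p_c = joint.sum(axis=0)
    h_l = -np.sum(p_l[p_l > 0] * np.log(p_l[p_l > 0]))
    h_c = -np.sum(p_c[p_c > 0] * np.log(p_c[p_c > 0]))
    if h_l + h_c == 0:
        warnings.warn("both partitions have a single category; NMI is degenerate (1.0)",
                      stacklevel=2)
        return 1.0
    nz = joint > 0
    mi = float(np.sum(joint[nz] * np.log(joint[nz] / np.outer(p_l, p_c)[nz])))
    return mi * 2.0 / (h_l + h_c)


def hopkins(points, m: int = 100, seed: int = 0, full_cov: bool = False) -> float:
    """Hopkins clusterability statistic, ``sum(u) / (sum(u) + sum(w))``.

    ``m`` reference points are drawn from a normal distribution matched to
    the dataset's moments — per-dimension mean and standard deviation by
    default, full covariance with ``full_cov=True``.  ``u_i`` is the
    distance from each reference point to its nearest data point; ``w_i``
    the distance from each of ``m`` data points (sampled without
    replacement) to its nearest *other* data point.  Values near 0.5 mean
    unstructured data; values toward 1 mean a discrete, clusterable set.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    n = len(points)
    if m > n - 1:
        raise ValueError(f"need at least m+1={m + 1} data points, got {n}")
    rng = np.random.default_rng(seed)
    if full_cov:
        synthetic = rng.multivariate_normal(points.mean(axis=0), np.cov(points.T), size=m)
    else:
        synthetic = rng.normal(points.mean(axis=0), points.std(axis=0), size=(m, points.shape[1]))
    tree = cKDTree(points)
    u = tree.query(synthetic, k=1)[0]
    sample_idx = rng.choice(n, size=m, replace=False)
    w = tree.query(points[sample_idx], k=2)[0][:, 1]  # k=1 is the point itself
    total = u.sum() + w.sum()
    return float(u.sum() / total) if total > 0 else 0.5


@dataclass
class AnnotationReport:
    """Annotation-effort metrics derived from one clustering run."""

    n_labels: int
    n_clusters: int
    pct_discriminant: float
    pct_clustered: float
    n_missed: int
    purity_threshold: float = 0.9

    def as_dict(self) -> dict:
        return {
            "n_labels": self.n_labels,
            "n_clusters": self.n_clusters,
            "pct_discriminant": self.pct_discriminant,
            "pct_clustered": self.pct_clustered,
            "n_missed": self.n_missed,
        }


def discriminant_report(clusters, labels, purity_threshold: float = 0.9) -> AnnotationReport:
    """Count discriminant clusters and the annotation effort they spare.

    A cluster is discriminant when the fraction of its *labelled* members
    belonging to the majority type is at least ``purity_threshold`` (the
    boundary is inclusive: exactly 90% counts).  Clusters containing only
    unlabelled vocalisations cannot be assessed and are excluded from the
    discriminant percentage; they still count in ``n_clusters``.
    ``pct_clustered`` is the share of *all* vocalisations (labelled or not)
    sitting in discriminant clusters; ``n_missed`` counts labels whose every
    occurrence falls outside them.
    """
    clusters = np.asarray(clusters)
    labels = np.asarray(labels, dtype=object)
    labelled = _is_labelled(labels)
    if not labelled.any():
        raise ValueError("no labelled vocalisations: cannot assess clusters")
    cluster_ids = sorted(set(clusters[clusters != NOISE]))

    discriminant: list[int] = []
    n_assessable = 0
    for cid in cluster_ids:
        member_labels = labels[(clusters == cid) & labelled]
        if len(member_labels) == 0:
            continue
        n_assessable += 1
        counts = pd.Series(member_labels).value_counts()
        if counts.iloc[0] / counts.sum() >= purity_threshold:
            discriminant.append(cid)
    if n_assessable == 0:
        raise ValueError("no cluster contains a labelled vocalisation")

    in_discr = np.isin(clusters, discriminant)
    all_labels = set(labels[labelled])
    covered = set(labels[in_discr & labelled])
    return AnnotationReport(
        n_labels=len(all_labels),
        n_clusters=len(cluster_ids),
        pct_discriminant=100.0 * len(discriminant) / n_assessable,
        pct_clustered=100.0 * in_discr.mean(),
        n_missed=len(all_labels - covered),
        purity_threshold=purity_threshold,
    )


def filter_rare_labels(table: pd.DataFrame, min_count: int = 20) -> pd.DataFrame:
    """Demote under-represented labels to unlabelled.

    Labels with fewer than ``min_count`` occurrences usually reflect
    labelling errors or types too rare to evaluate against; their rows are
    kept but marked unlabelled.  The boundary reads "fewer than": exactly
    ``min_count`` occurrences is kept.
    """
    table = table.copy()
    if len(table) == 0 or "label" not in table.columns:
        return table
    counts = table["label"].value_counts()
    rare = counts.index[counts < min_count]
    table.loc[table["label"].isin(rare), "label"] = pd.NA
    return table
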