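"""End-to-end repertoire discovery: audio + annotations → clusters + metrics.

One call runs the whole chain — rare-label filtering, spectrogram batch,
auto-encoder training, bottleneck encoding, UMAP projection, HDBSCAN
clustering — and scores it (NMI against expert labels, Hopkins
clusterability on the 2-D projection, discriminant-cluster report).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .autoencoder import ConvAutoEncoder, TrainResult, train
from .config import AutoEncoderSpec, SpectrogramConfig, TrainConfig
from .evaluation import discriminant_report, filter_rare_labels, hopkins, nmi
from .preprocessing import SpectrogramBatch, build_batch
from .projection import ClusterAssignment, ClusterParams, cluster, project

__all__ = ["PipelineResult", "encode_batch", "run_pipeline"]


def encode_batch(model: ConvAutoEncoder, values: np.ndarray, chunk: int = 64) -> np.ndarray:
    """Bottleneck embeddings for a stack of spectrograms, in memory-bounded chunks."""
    parts = [model.encode(values[i : i + chunk]) for i in range(0, len(values), chunk)]
    return np.concatenate(parts, axis=0)


@dataclass
class PipelineResult:
    table: pd.DataFrame
    batch: SpectrogramBatch
    train_result: TrainResult
    embeddings: np.ndarray
    projected: np.ndarray
    assignment: ClusterAssignment
    metrics: dict = field(default_factory=dict)


def run_pipeline(
    table: pd.DataFrame,
    spectro_config: SpectrogramConfig,
    audio_root: str | Path = ".",
    ae_spec: AutoEncoderSpec | None = None,
    train_config: TrainConfig | None = None,
    cluster_params: ClusterParams | None = None,
    umap_dims: int = 8,
    seed: int = 0,
    min_label_count: int = 20,
    hopkins_m: int = 100,
) -> PipelineResult:
    """Run the full repertoire-discovery pipeline and score it.

    ``seed`` drives UMAP and the Hopkins reference draw; auto-encoder
    training takes its own seed from ``train_config``.  Labels occurring
    fewer than ``min_label_count`` times are demoted to unlabelled before
    anything else, mirroring how rare / mislabelled types are handled in
    evaluation.  The Hopkins statistic is computed on a 2-D UMAP view (the
    space in which repertoire discreteness is usually inspected).
    """
    ae_spec = ae_spec or AutoEncoderSpec()
    train_config = train_config or TrainConfig(seed=seed)
    cluster_params = cluster_params or ClusterParams()

    table = filter_rare_labels(table, min_count=min_label_count)
    batch = build_batch(table, spectro_config, audio_root=audio_root)
    result = train(batch.values, ae_spec, train_config)
    embeddings = encode_batch(result.model, batch.values)
    projected = project(embeddings, n_dims=umap_dims, seed=seed)
    assignment = cluster(projected, cluster_params)

    labels = table["label"].to_numpy(dtype=object)
    view2d = projected if umap_dims == 2 else project(embeddings, n_dims=2, seed=seed)
    m = min(hopkins_m, len(embeddings) - 1)
    report = discriminant_report(assignment.labels, labels)
    metrics = {
        "n_vocalisations": int(len(table)),
        "nmi": nmi(labels, assignment.labels),
        "hopkins": hopkins(view2d, m=m, seed=seed),
        "n_noise": assignment.n_noise,
        "train_steps": int(len(result.history)),
        **report.as_dict(),
    }
    return PipelineResult(table, batch, result, embeddings, projected, assignment, metrics)
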