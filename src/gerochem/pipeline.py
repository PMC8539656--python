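"""End-to-end orchestration helpers tying the stages together.

These are thin conveniences over the module functions — the same calls a
user would write by hand — used by the CLI and by whole-pipeline tests:
generate/load a world, featurize it, label a direction, assemble one of
the eight model layouts, and train.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from . import descriptors, ingest
from .datasets import AssembledDataset, FeatureBundle, ModelSpec, assemble, balance, kfold
from .descriptors import FcbfResult
from .learners import DnnConfig, EvalReport, TrainedClassifier, train_classifier
from .synthgen import SyntheticWorld

logger = logging.getLogger(__name__)

__all__ = ["featurize_world", "label_world", "run_model"]


def featurize_world(world: SyntheticWorld, delta: float = 0.6,
                    min_genes: int = 3, radius: int = 2, n_bits: int = 2048,
                    alpha: float = descriptors.DEFAULT_ALPHA,
                    n_bins: int = 3) -> tuple[FeatureBundle, FcbfResult]:
    """Build all four descriptor blocks for a world."""
    ann = descriptors.annotation_map(world.go_annotations)
    genes = sorted(set(world.perturbations["gene_symbol"])
                   | set(world.longevity["gene_symbol"])) or sorted(ann)
    gene_go = descriptors.build_go_matrix(ann, genes, min_genes=min_genes)
    drug_fp, _failed = descriptors.fingerprint_table(world.smiles, radius=radius,
                                                    n_bits=n_bits)
    beta = descriptors.beta_matrix(world.intensities_meth, world.intensities_unmeth,
                                   alpha=alpha)
    disc = descriptors.discretize_beta(beta, n_bins=n_bins)
    hist = world.histology.set_index("cell_line").loc[beta.index, "histology"]
    fcbf = descriptors.fcbf_select(disc, hist.to_numpy(), delta=delta)
    bundle = FeatureBundle(gene_go=gene_go, drug_fp=drug_fp,
                           cell_mut=world.mutations,
                           cell_beta=beta.loc[:, fcbf.selected])
    return bundle, fcbf


def label_world(world: SyntheticWorld, direction: str,
                fraction: float = 0.05) -> pd.DataFrame:
    """Standard record pipeline: 24 h/µM filter, longevity-gene restriction,
    per-cell-line percentile labeling."""
    records = ingest.filter_records(world.perturbations)
    longevity = dict(zip(world.longevity["gene_symbol"], world.longevity["effect"]))
    records = ingest.restrict_genes(records, longevity)
    return ingest.label_direction(records, direction, fraction=fraction)


@dataclass
class ModelRun:
    spec: ModelSpec
    dataset: AssembledDataset
    trained: TrainedClassifier
    fold_reports: list[EvalReport]


def run_model(world: SyntheticWorld, spec: ModelSpec, bundle: FeatureBundle,
              kind: str = "dnn", fraction: float = 0.05, k: int = 3,
              config: DnnConfig | None = None, seed: int = 0) -> ModelRun:
    """Label, assemble, (optionally) balance, split, and train one layout."""
    labeled = label_world(world, spec.direction, fraction=fraction)
    dataset = assemble(spec, labeled, bundle)
    if spec.balanced:
        dataset = balance(dataset, seed=seed)
    folds = kfold(dataset, k=k, seed=seed)
    config = config or DnnConfig(seed=seed)
    trained, reports = train_classifier(kind, dataset, folds, config)
    trained.metadata.update(model_id=spec.model_id, direction=spec.direction,
                            feature_type=spec.feature_type)
    return ModelRun(spec=spec, dataset=dataset, trained=trained, fold_reports=reports)
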