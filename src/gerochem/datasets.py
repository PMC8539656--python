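"""Assembly of drug–gene–cell feature matrices for the eight model layouts.

The eight configurations differ along three axes:

====== ========== ================= ========= =============
model  direction  cell scope        balanced  feature type
====== ========== ================= ========= =============
1      up         all cell lines    yes       1
2      down       all cell lines    yes       1
3      up         two-line subset   no        1
4      down       two-line subset   no        1
5      up         two-line subset   no        2
6      down       two-line subset   no        2
7      up         two-line subset   no        3
8      down       two-line subset   no        3
====== ========== ================= ========= =============

Feature types: 1 = GO + fingerprint + mutation + methylation,
2 = GO + fingerprint + mutation, 3 = GO + fingerprint + methylation.
Blocks are always concatenated gene | drug | cell (mutation before
methylation).  Balancing downsamples negatives to the positive count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "FeatureBundle",
    "AssembledDataset",
    "make_model_specs",
    "assemble",
    "balance",
    "kfold",
]

#: feature_type → (include mutation block, include methylation block)
FEATURE_TYPE_BLOCKS = {1: (True, True), 2: (True, False), 3: (False, True)}

#: the two low-volume cell lines the subset models train on in the real study
DEFAULT_SUBSET_CELLS = ("U266", "NOMO1")


@dataclass(frozen=True)
class ModelSpec:
    """One row of the eight-model layout."""

    model_id: int
    direction: str              # "up" or "down"
    cell_scope: tuple | None    # None = all cell lines, else the named subset
    balanced: bool
    feature_type: int           # key into FEATURE_TYPE_BLOCKS

    def __post_init__(self):
        if self.direction not in {"up", "down"}:
            raise ValueError(f"direction must be 'up'/'down', got {self.direction!r}")
        if self.feature_type not in FEATURE_TYPE_BLOCKS:
            raise ValueError(f"feature_type must be 1, 2 or 3, got {self.feature_type}")


def make_model_specs(subset_cells=DEFAULT_SUBSET_CELLS) -> list[ModelSpec]:
    """The eight model layouts; ``subset_cells`` names the two-line subset
    (overridable for synthetic worlds whose cells are named differently)."""
    subset = tuple(subset_cells)
    return [
        ModelSpec(1, "up", None, True, 1),
        ModelSpec(2, "down", None, True, 1),
        ModelSpec(3, "up", subset, False, 1),
        ModelSpec(4, "down", subset, False, 1),
        ModelSpec(5, "up", subset, False, 2),
        ModelSpec(6, "down", subset, False, 2),
        ModelSpec(7, "up", subset, False, 3),
        ModelSpec(8, "down", subset, False, 3),
    ]


@dataclass
class FeatureBundle:
    """The four descriptor matrices keyed by entity id.

    gene_go:    gene × GO-term one-hot
    drug_fp:    drug × fingerprint-bit
    cell_mut:   cell × mutation-marker binary
    cell_beta:  cell × FCBF-selected CpG site beta values (selection order)
    """

    gene_go: pd.DataFrame
    drug_fp: pd.DataFrame
    cell_mut: pd.DataFrame
    cell_beta: pd.DataFrame

    def width(self, feature_type: int) -> int:
        mut, meth = FEATURE_TYPE_BLOCKS[feature_type]
        return (self.gene_go.shape[1] + self.drug_fp.shape[1]
                + (self.cell_mut.shape[1] if mut else 0)
                + (self.cell_beta.shape[1] if meth else 0))

    def column_names(self, feature_type: int) -> list[str]:
        mut, meth = FEATURE_TYPE_BLOCKS[feature_type]
        cols = [f"go|{t}" for t in self.gene_go.columns]
        cols += [f"fp|{b}" for b in self.drug_fp.columns]
        if mut:
            cols += [f"mut|{m}" for m in self.cell_mut.columns]
        if meth:
            cols += [f"meth|{s}" for s in self.cell_beta.columns]
        return cols


@dataclass
class AssembledDataset:
    """Feature matrix + binary target + per-row (drug, gene, cell) keys."""

    X: np.ndarray
    y: np.ndarray
    keys: pd.DataFrame  # drug_id, gene_symbol, cell_line

    def __post_init__(self):
        if not (len(self.X) == len(self.y) == len(self.keys)):
            raise ValueError("X, y and keys must have equal row counts")

    @property
    def n_samples(self) -> int:
        return len(self.y)

    @property
    def width(self) -> int:
        return self.X.shape[1]


def _dedup_extreme(labeled: pd.DataFrame, direction: str) -> pd.DataFrame:
    """Collapse dose replicates of the same (drug, gene, cell) triple,
    keeping the record with the extreme Z for the model's direction
    (max Z for up, min Z for down).  Prevents identical feature rows
    carrying conflicting labels."""
    before = len(labeled)
    idx = (labeled.sort_values("z_score", ascending=(direction == "down"), kind="mergesort")
           .drop_duplicates(["drug_id", "gene_symbol", "cell_line"], keep="first").index)
    out = labeled.loc[labeled.index.isin(idx)]
    if len(out) != before:
        logger.info("assemble: collapsed %d dose-replicate row(s)", before - len(out))
    return out


def assemble(spec: ModelSpec, labeled: pd.DataFrame, bundle: FeatureBundle,
             dedup: bool = True) -> AssembledDataset:
    """Build the feature matrix for one model layout.

    ``labeled`` is the output of the direction labeler and must match
    ``spec.direction``.  Rows are restricted to ``spec.cell_scope``,
    dose replicates collapsed to the extreme-Z record (switchable), and
    samples whose drug/gene/cell lacks a descriptor are dropped with a
    logged count.  Rows are ordered by sorted (drug, gene, cell) key.
    """
    if not labeled.empty and set(labeled["direction"]) != {spec.direction}:
        raise ValueError(
            f"labeled direction(s) {sorted(set(labeled['direction']))} do not "
            f"match spec direction {spec.direction!r}")

    df = labeled
    if spec.cell_scope is not None and not df.empty:
        df = df.loc[df["cell_line"].isin(set(spec.cell_scope))]
    if dedup and not df.empty:
        df = _dedup_extreme(df, spec.direction)
    if not df.empty:
        df = df.sort_values(["drug_id", "gene_symbol", "cell_line"], kind="mergesort")

    known = (df["gene_symbol"].isin(bundle.gene_go.index)
             & df["drug_id"].isin(bundle.drug_fp.index)
             & df["cell_line"].isin(bundle.cell_mut.index)
             & df["cell_line"].isin(bundle.cell_beta.index)) if not df.empty else df.index
    if not df.empty:
        dropped = int((~known).sum())
        if dropped:
            logger.warning("assemble: dropped %d sample(s) lacking a descriptor", dropped)
        df = df.loc[known]

    width = bundle.width(spec.feature_type)
    if df.empty:
        return AssembledDataset(np.zeros((0, width)), np.zeros(0, dtype=int),
                                pd.DataFrame(columns=["drug_id", "gene_symbol", "cell_line"]))

    mut, meth = FEATURE_TYPE_BLOCKS[spec.feature_type]
    blocks = [bundle.gene_go.loc[df["gene_symbol"]].to_numpy(dtype=float),
              bundle.drug_fp.loc[df["drug_id"]].to_numpy(dtype=float)]
    if mut:
        blocks.append(bundle.cell_mut.loc[df["cell_line"]].to_numpy(dtype=float))
    if meth:
        blocks.append(bundle.cell_beta.loc[df["cell_line"]].to_numpy(dtype=float))
    X = np.hstack(blocks) if blocks else np.zeros((len(df), 0))
    y = df["is_positive"].to_numpy(dtype=int)
    keys = df[["drug_id", "gene_symbol", "cell_line"]].reset_index(drop=True)
    return AssembledDataset(X, y, keys)


def balance(dataset: AssembledDataset, seed: int) -> AssembledDataset:
    """Downsample negatives (uniform, without replacement) to the positive
    count; all positives are kept.  Output row order follows the input."""
    pos = np.flatnonzero(dataset.y == 1)
    neg = np.flatnonzero(dataset.y == 0)
    if len(pos) == 0:
        raise ValueError("cannot balance a dataset with zero positive samples")
    rng = np.random.default_rng(seed)
    take_neg = rng.choice(neg, size=min(len(pos), len(neg)), replace=False)
    keep = np.sort(np.concatenate([pos, take_neg]))
    return AssembledDataset(dataset.X[keep], dataset.y[keep],
                            dataset.keys.iloc[keep].reset_index(drop=True))


def kfold(dataset: AssembledDataset, k: int = 3, seed: int = 0
          ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified k-fold partition: list of (train_idx, val_idx) pairs,
    disjoint and exhaustive over the rows."""
    if dataset.n_samples < k:
        raise ValueError(f"need at least k={k} rows, have {dataset.n_samples}")
    n_min = int(min(np.bincount(dataset.y, minlength=2)))
    if n_min < k:
        raise ValueError(
            f"minority class has {n_min} sample(s), fewer than k={k}; "
            f"use a smaller k")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr, va) for tr, va in skf.split(dataset.X, dataset.y)]
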