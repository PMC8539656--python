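"""Drug-repurposing logic: interaction counting, ranking, prediction pools.

A drug's repurposing evidence is its set of desired-direction positive
(gene, cell line) pairs — upregulation of pro-longevity genes or
downregulation of anti-longevity genes.  Drugs are ranked by the number
of such unique pairs ("interactions"), subject to diversity filters
requiring strictly more than ``min_genes`` distinct genes and strictly
more than ``min_cells`` distinct cell lines.  The up- and down-ranking
intersection yields dual-action candidates.

For prospective scoring on normal (non-cancer) cell lines, each
candidate drug gets a pool: its full Cartesian product with the relevant
longevity genes and the normal lines.  A trained classifier scores every
triple; the per-drug positive rate (fraction of triples at or above the
probability threshold) summarizes repurposing promise.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import FEATURE_TYPE_BLOCKS, FeatureBundle
from .learners import TrainedClassifier, predict_proba

logger = logging.getLogger(__name__)

__all__ = [
    "DrugRankEntry",
    "PredictionPool",
    "collect_interactions",
    "rank_drugs",
    "intersect_rankings",
    "build_pool",
    "score_pool",
    "export_edges",
]

#: desired mode → (label direction, longevity label)
DESIRED_MODES = {"up-on-pro": ("up", "pro"), "down-on-anti": ("down", "anti")}


@dataclass(frozen=True)
class DrugRankEntry:
    drug_id: str
    n_interactions: int   # unique positive (gene, cell) pairs
    n_unique_genes: int
    n_unique_cells: int


@dataclass(frozen=True)
class PredictionPool:
    """Cartesian product of candidate drugs × longevity genes × normal cells."""

    drugs: tuple
    genes: tuple
    cells: tuple
    triples: pd.DataFrame  # drug_id, gene_symbol, cell_line (lexical order)

    @property
    def size(self) -> int:
        return len(self.triples)


def collect_interactions(labeled: pd.DataFrame, longevity: dict[str, str],
                         desired: str) -> dict[str, set[tuple[str, str]]]:
    """Per-drug set of desired positive (gene, cell) pairs.

    ``desired`` is ``"up-on-pro"`` (upregulation positives on
    pro-longevity genes) or ``"down-on-anti"``.  The labeled table's
    direction must match the mode.  Replicate positives of the same
    (drug, gene, cell) triple collapse into one pair.
    """
    if desired not in DESIRED_MODES:
        raise ValueError(f"desired must be one of {sorted(DESIRED_MODES)}, got {desired!r}")
    direction, want_label = DESIRED_MODES[desired]
    if not labeled.empty and set(labeled["direction"]) != {direction}:
        raise ValueError(
            f"labeled direction(s) {sorted(set(labeled['direction']))} inconsistent "
            f"with mode {desired!r} (needs {direction!r})")

    out: dict[str, set[tuple[str, str]]] = {}
    if labeled.empty:
        return out
    pos = labeled.loc[labeled["is_positive"]]
    for drug, gene, cell in zip(pos["drug_id"], pos["gene_symbol"], pos["cell_line"]):
        if longevity.get(gene) == want_label:
            out.setdefault(drug, set()).add((gene, cell))
    return out


def rank_drugs(interactions: dict[str, set[tuple[str, str]]],
               min_genes: int = 100, min_cells: int = 5,
               top_k: int = 10) -> list[DrugRankEntry]:
    """Rank drugs by unique-interaction count under the diversity filter.

    A drug qualifies only with strictly more than ``min_genes`` distinct
    genes and strictly more than ``min_cells`` distinct cell lines among
    its positive pairs.  Sorted by interaction count descending, ties by
    drug id, truncated to ``top_k``.
    """
    entries = []
    for drug, pairs in interactions.items():
        genes = {g for g, _ in pairs}
        cells = {c for _, c in pairs}
        if len(genes) > min_genes and len(cells) > min_cells:
            entries.append(DrugRankEntry(drug, len(pairs), len(genes), len(cells)))
    entries.sort(key=lambda e: (-e.n_interactions, e.drug_id))
    return entries[:top_k]


def intersect_rankings(up_rank: list[DrugRankEntry],
                       down_rank: list[DrugRankEntry]) -> list[str]:
    """Drugs present in both rankings (the dual-action candidates),
    ordered by combined interaction count descending, ties by drug id."""
    up = {e.drug_id: e.n_interactions for e in up_rank}
    down = {e.drug_id: e.n_interactions for e in down_rank}
    common = set(up) & set(down)
    return sorted(common, key=lambda d: (-(up[d] + down[d]), d))


def build_pool(drugs, genes, cells) -> PredictionPool:
    """Full lexically-ordered Cartesian product of the three axes."""
    axes = {"drugs": sorted(drugs), "genes": sorted(genes), "cells": sorted(cells)}
    for name, vals in axes.items():
        if not vals:
            raise ValueError(f"pool axis {name!r} is empty")
    triples = pd.DataFrame(
        itertools.product(axes["drugs"], axes["genes"], axes["cells"]),
        columns=["drug_id", "gene_symbol", "cell_line"])
    return PredictionPool(tuple(axes["drugs"]), tuple(axes["genes"]),
                          tuple(axes["cells"]), triples)


def _pool_features(pool: PredictionPool, bundle: FeatureBundle, feature_type: int,
                   normal_cells: set) -> np.ndarray:
    for d in pool.drugs:
        if d not in bundle.drug_fp.index:
            raise KeyError(f"no fingerprint descriptor for drug {d!r}")
    for g in pool.genes:
        if g not in bundle.gene_go.index:
            raise KeyError(f"no GO descriptor for gene {g!r}")
    mut, meth = FEATURE_TYPE_BLOCKS[feature_type]
    for c in pool.cells:
        if mut and c not in normal_cells and c not in bundle.cell_mut.index:
            raise KeyError(f"no mutation profile for cell line {c!r}")
        if meth and c not in bundle.cell_beta.index:
            raise KeyError(f"no methylation profile for cell line {c!r}")

    df = pool.triples
    blocks = [bundle.gene_go.loc[df["gene_symbol"]].to_numpy(dtype=float),
              bundle.drug_fp.loc[df["drug_id"]].to_numpy(dtype=float)]
    if mut:
        # normal lines carry no mutation annotation: all-zero block
        mut_rows = np.zeros((len(df), bundle.cell_mut.shape[1]))
        cancer = ~df["cell_line"].isin(normal_cells).to_numpy()
        if cancer.any():
            mut_rows[cancer] = bundle.cell_mut.loc[
                df.loc[cancer, "cell_line"]].to_numpy(dtype=float)
        blocks.append(mut_rows)
    if meth:
        blocks.append(bundle.cell_beta.loc[df["cell_line"]].to_numpy(dtype=float))
    return np.hstack(blocks)


def score_pool(model: TrainedClassifier, pool: PredictionPool,
               bundle: FeatureBundle, feature_type: int = 1,
               normal_cells=(), threshold: float = 0.5) -> pd.DataFrame:
    """Score every pool triple and summarize positives per drug.

    Cells listed in ``normal_cells`` get an all-zero mutation block; their
    beta values must cover every site the bundle carries (no imputation).
    Returns one row per drug: pool_size, n_positive, positive_rate,
    n_unique_positive_genes.
    """
    X = _pool_features(pool, bundle, feature_type, set(normal_cells))
    scores = predict_proba(model, X)
    df = pool.triples.copy()
    df["positive"] = scores >= threshold

    rows = []
    for drug in pool.drugs:
        sub = df.loc[df["drug_id"] == drug]
        pos = sub.loc[sub["positive"]]
        rows.append({
            "drug_id": drug,
            "pool_size": len(sub),
            "n_positive": len(pos),
            "positive_rate": len(pos) / len(sub) if len(sub) else float("nan"),
            "n_unique_positive_genes": pos["gene_symbol"].nunique(),
        })
    return pd.DataFrame(rows)


def export_edges(interactions: dict[str, set[tuple[str, str]]],
                 path: str | Path) -> pd.DataFrame:
    """Plain edge-list export (drug, gene, n_cell_lines) of the interaction
    map, for external network/chord visualization."""
    rows = []
    for drug, pairs in sorted(interactions.items()):
        per_gene: dict[str, int] = {}
        for gene, _cell in pairs:
            per_gene[gene] = per_gene.get(gene, 0) + 1
        for gene, n in sorted(per_gene.items()):
            rows.append((drug, gene, n))
    df = pd.DataFrame(rows, columns=["drug_id", "gene_symbol", "n_cell_lines"])
    df.to_csv(path, sep="\t", index=False)
    return df
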