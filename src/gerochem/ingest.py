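"""Perturbation-record ingestion, filtering, and direction labeling.

The labeling convention is the left–right percentile rule: within each
cell line, the records with the top ``fraction`` of Z-scores are the
positive class of the upregulation model, and the records with the
bottom ``fraction`` are the positive class of the downregulation model.
All remaining records — regulation status unknown — form the negative
class of each model.
"""

from __future__ import annotations

import logging
import math
import unicodedata
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PERTURBATION_COLUMNS",
    "MalformedRecordError",
    "load_perturbations",
    "load_longevity",
    "filter_records",
    "restrict_genes",
    "label_direction",
]

PERTURBATION_COLUMNS = (
    "drug_id", "gene_symbol", "cell_line",
    "dose_value", "dose_unit", "time_h", "z_score",
)

_NUMERIC = ("dose_value", "time_h", "z_score")


class MalformedRecordError(ValueError):
    """Raised when rows carry non-finite or unparseable numeric fields.

    Carries the offending 0-based row indices in ``rows``.
    """

    def __init__(self, message: str, rows: list[int]):
        super().__init__(message)
        self.rows = rows


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def load_perturbations(path: str | Path) -> pd.DataFrame:
    """Load a long-format perturbation table (TSV or CSV by extension).

    Requires the columns in :data:`PERTURBATION_COLUMNS`.  Numeric fields
    must parse to finite values and ``time_h`` must be positive; offending
    rows are reported by 0-based index via :class:`MalformedRecordError`.
    """
    df = _read_table(path)
    missing = [c for c in PERTURBATION_COLUMNS if c not in df.columns]
    if missing:
        raise KeyError(f"perturbation table {path} is missing required column(s): {missing}")
    df = df.loc[:, list(PERTURBATION_COLUMNS)].copy()
    bad: set[int] = set()
    for col in _NUMERIC:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad.update(df.index[~np.isfinite(vals)].tolist())
        df[col] = vals
    bad.update(df.index[df["time_h"] <= 0].tolist())
    if bad:
        rows = sorted(bad)
        raise MalformedRecordError(
            f"{len(rows)} row(s) with non-finite or invalid numeric fields "
            f"(first offenders: {rows[:10]})", rows)
    return df.reset_index(drop=True)


def load_longevity(path: str | Path) -> dict[str, str]:
    """Load the gene → {pro, anti} label table (columns gene_symbol, effect)."""
    df = _read_table(path)
    for col in ("gene_symbol", "effect"):
        if col not in df.columns:
            raise KeyError(f"longevity table {path} is missing required column: {col!r}")
    bad = sorted(set(df["effect"]) - {"pro", "anti"})
    if bad:
        raise ValueError(f"longevity effect labels must be 'pro' or 'anti', got {bad}")
    dup = df["gene_symbol"][df["gene_symbol"].duplicated()].unique()
    if len(dup):
        raise ValueError(f"genes with more than one longevity label: {list(dup)[:10]}")
    return dict(zip(df["gene_symbol"], df["effect"]))


def _norm_unit(unit: str) -> str:
    # NFKC folds MICRO SIGN (U+00B5) and GREEK MU (U+03BC) to one codepoint,
    # so "µM" matches however the micro sign was typed.
    return unicodedata.normalize("NFKC", str(unit))


def filter_records(records: pd.DataFrame, time_h: float = 24.0,
                   dose_unit: str = "µM") -> pd.DataFrame:
    """Keep only records at exactly ``time_h`` hours and ``dose_unit`` dose.

    The unit comparison is an exact string match after Unicode
    normalization of the micro sign.  Input row order is preserved.
    """
    if records.empty:
        return records.copy()
    want = _norm_unit(dose_unit)
    keep = (records["time_h"] == time_h) & (records["dose_unit"].map(_norm_unit) == want)
    out = records.loc[keep].reset_index(drop=True)
    logger.info("filter_records: kept %d of %d records (%.1f h, unit %s)",
                len(out), len(records), time_h, dose_unit)
    return out


def restrict_genes(records: pd.DataFrame, genes) -> pd.DataFrame:
    """Keep records whose gene_symbol is in ``genes`` (a longevity label
    mapping or any container of symbols)."""
    gene_set = set(genes)
    if records.empty:
        return records.copy()
    return records.loc[records["gene_symbol"].isin(gene_set)].reset_index(drop=True)


def label_direction(records: pd.DataFrame, direction: str,
                    fraction: float = 0.05) -> pd.DataFrame:
    """Label records positive/negative by the per-cell-line percentile rule.

    Within each cell line independently, exactly ``floor(fraction * n)``
    records are positive: the k largest Z-scores for ``direction="up"``,
    the k smallest for ``direction="down"``.  Ties are broken by
    (drug_id, gene_symbol) lexical order, which makes the labeling
    invariant to input row order.  Everything else is negative.

    Returns a copy of ``records`` with ``direction`` and ``is_positive``
    columns appended, input row order preserved.
    """
    if direction not in {"up", "down"}:
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    if not (0.0 < fraction < 0.5):
        raise ValueError(f"fraction must lie in (0, 0.5), got {fraction}")

    out = records.copy()
    out["direction"] = direction
    is_pos = np.zeros(len(out), dtype=bool)

    for _, grp in out.groupby("cell_line", sort=False):
        n = len(grp)
        k = int(math.floor(fraction * n + 1e-9))
        if n == 0 or k == 0:
            continue
        ascending = direction == "down"
        order = grp.sort_values(
            ["z_score", "drug_id", "gene_symbol"],
            ascending=[ascending, True, True],
            kind="mergesort",
        )
        is_pos[out.index.get_indexer(order.index[:k])] = True

    out["is_positive"] = is_pos
    return out
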