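"""Feature construction: the four descriptor blocks.

* gene block  — one-hot Gene Ontology membership, restricted to terms
  annotating at least ``min_genes`` of the genes under study;
* drug block  — radius-2 Morgan (circular substructure) fingerprints
  folded to a fixed bit length;
* cell block, part 1 — binary mutation-marker status;
* cell block, part 2 — CpG methylation beta values, reduced to the sites
  a fast correlation-based filter (FCBF) selects as relevant to cell-line
  histology.

The beta value at probe j is max(meth,0) / (max(meth,0) + max(unmeth,0) + α),
with α > 0 guarding the division; α defaults to 100, the Illumina-
recommended stabilizer for BeadChip intensities.

FCBF's "correlation" is symmetrical uncertainty, SU(x, y) =
2·I(x;y) / (H(x) + H(y)), computed with plug-in entropies in bits on
discretized variables.  Sites are ranked by SU against the histology
class, thresholded at ``delta``, then scanned in rank order removing any
site dominated by a stronger already-kept site (SU(kept, site) ≥
SU(site, class)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator

logger = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.error")  # unparseable SMILES reported via exceptions

__all__ = [
    "FingerprintError",
    "build_go_matrix",
    "fingerprint",
    "fingerprint_table",
    "compute_beta",
    "beta_matrix",
    "discretize_beta",
    "symmetrical_uncertainty",
    "FcbfResult",
    "fcbf_select",
    "build_cell_descriptor",
]

DEFAULT_ALPHA = 100.0


# ---------------------------------------------------------------------------
# Gene block: GO one-hot
# ---------------------------------------------------------------------------


def build_go_matrix(annotations: dict[str, set[str]], genes,
                    min_genes: int = 3) -> pd.DataFrame:
    """One-hot gene × GO-term matrix over the given gene list.

    The term vocabulary keeps exactly the terms annotating at least
    ``min_genes`` of ``genes``, sorted lexically.  Genes absent from the
    annotation map get an all-zero row (logged).
    """
    genes = list(genes)
    if not genes:
        raise ValueError("genes must be nonempty")
    counts: dict[str, int] = {}
    for g in genes:
        for t in annotations.get(g, ()):
            counts[t] = counts.get(t, 0) + 1
    vocab = sorted(t for t, c in counts.items() if c >= min_genes)
    col = {t: j for j, t in enumerate(vocab)}
    mat = np.zeros((len(genes), len(vocab)), dtype=np.int8)
    n_missing = 0
    for i, g in enumerate(genes):
        terms = annotations.get(g)
        if not terms:
            n_missing += 1
            continue
        for t in terms:
            j = col.get(t)
            if j is not None:
                mat[i, j] = 1
    if n_missing:
        logger.warning("build_go_matrix: %d of %d genes have no annotations "
                       "(all-zero descriptor rows)", n_missing, len(genes))
    return pd.DataFrame(mat, index=pd.Index(genes, name="gene_symbol"), columns=vocab)


def annotation_map(go_long: pd.DataFrame) -> dict[str, set[str]]:
    """Long two-column (gene_symbol, go_term) table → gene → term-set map."""
    out: dict[str, set[str]] = {}
    for g, t in zip(go_long["gene_symbol"], go_long["go_term"]):
        out.setdefault(g, set()).add(t)
    return out


# ---------------------------------------------------------------------------
# Drug block: Morgan fingerprints
# ---------------------------------------------------------------------------


class FingerprintError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecule."""


def fingerprint(smiles: str, radius: int = 2, n_bits: int = 2048) -> np.ndarray:
    """Binary Morgan fingerprint of one molecule, folded to ``n_bits``.

    The SMILES is parsed to a molecule object before hashing, so any two
    SMILES of the same structure (e.g. kekulized vs aromatic benzene)
    yield identical vectors.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise FingerprintError(f"unparseable SMILES: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    return np.asarray(gen.GetFingerprintAsNumPy(mol), dtype=np.int8)


def fingerprint_table(smiles: pd.DataFrame, radius: int = 2,
                      n_bits: int = 2048) -> tuple[pd.DataFrame, list[str]]:
    """Fingerprints for a (drug_id, smiles) table.

    Returns the drug × bit matrix and the list of drug_ids whose SMILES
    failed to parse (excluded from the matrix, logged).
    """
    rows, index, failed = [], [], []
    for drug_id, smi in zip(smiles["drug_id"], smiles["smiles"]):
        try:
            rows.append(fingerprint(smi, radius=radius, n_bits=n_bits))
            index.append(drug_id)
        except FingerprintError:
            failed.append(drug_id)
    if failed:
        logger.warning("fingerprint_table: %d drug(s) with unparseable SMILES "
                       "excluded: %s", len(failed), failed[:10])
    mat = np.vstack(rows) if rows else np.zeros((0, n_bits), dtype=np.int8)
    return pd.DataFrame(mat, index=pd.Index(index, name="drug_id"),
                        columns=range(n_bits)), failed


# ---------------------------------------------------------------------------
# Cell block: methylation beta values
# ---------------------------------------------------------------------------


def compute_beta(meth, unmeth, alpha: float = DEFAULT_ALPHA):
    """Beta value: max(meth,0) / (max(meth,0) + max(unmeth,0) + alpha).

    Vectorized over array inputs; negative intensities are clamped to 0.
    For alpha > 0 the result always lies in [0, 1).
    """
    if not alpha > 0:
        raise ValueError(f"alpha must be > 0, got {alpha}")
    m = np.maximum(np.asarray(meth, dtype=float), 0.0)
    u = np.maximum(np.asarray(unmeth, dtype=float), 0.0)
    return m / (m + u + alpha)


def beta_matrix(meth: pd.DataFrame, unmeth: pd.DataFrame,
                alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Per-(cell line, CpG site) beta values from paired intensity matrices."""
    if not meth.index.equals(unmeth.index) or not meth.columns.equals(unmeth.columns):
        raise ValueError("methylated/unmethylated matrices must share index and columns")
    return pd.DataFrame(compute_beta(meth.to_numpy(), unmeth.to_numpy(), alpha),
                        index=meth.index, columns=meth.columns)


def discretize_beta(beta: pd.DataFrame, n_bins: int = 3) -> pd.DataFrame:
    """Equal-width binning of beta values on [0, 1] (FCBF needs discrete
    variables).  Bin ids are 0 .. n_bins-1; the value 1.0 falls in the
    last bin."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    codes = np.minimum((beta.to_numpy() * n_bins).astype(int), n_bins - 1)
    return pd.DataFrame(codes, index=beta.index, columns=beta.columns)


# ---------------------------------------------------------------------------
# Symmetrical uncertainty and FCBF
# ---------------------------------------------------------------------------


def _entropy_bits(codes: np.ndarray) -> float:
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def symmetrical_uncertainty(x, y) -> float:
    """SU(x, y) = 2·I(x;y) / (H(x) + H(y)), in [0, 1].

    Plug-in entropies in bits over the empirical joint distribution.
    Returns 0 when either variable is constant (zero entropy), the
    standard convention for a variable carrying no information.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    hx = _entropy_bits(x)
    hy = _entropy_bits(y)
    if hx == 0.0 or hy == 0.0:
        return 0.0
    # joint entropy via paired codes
    _, pair_codes = np.unique(np.stack([_codes(x), _codes(y)]), axis=1, return_inverse=True)
    hxy = _entropy_bits(pair_codes)
    mi = hx + hy - hxy
    su = 2.0 * mi / (hx + hy)
    return float(min(max(su, 0.0), 1.0))


def _codes(v: np.ndarray) -> np.ndarray:
    _, inv = np.unique(v, return_inverse=True)
    return inv


@dataclass
class FcbfResult:
    """Outcome of FCBF selection.

    ``selected`` holds site identifiers in selection (relevance) order;
    ``relevance`` maps every candidate site to SU(site, class).
    """

    selected: list
    relevance: dict

    def selected_relevance(self) -> list[float]:
        return [self.relevance[s] for s in self.selected]


def fcbf_select(sites: pd.DataFrame, class_labels, delta: float = 0.6) -> FcbfResult:
    """Fast correlation-based filter over a discretized cell × site matrix.

    ``class_labels`` gives one discrete class (here: histology) per cell,
    aligned with ``sites``' rows.  Sites with SU against the class below
    ``delta`` are dropped; the survivors are scanned in descending
    relevance (ties by site id) and a site is removed if some
    stronger already-kept site predicts it at least as well as it
    predicts the class.  An empty selection is valid (logged).
    """
    y = np.asarray(class_labels)
    if len(sites) < 2:
        raise ValueError("need at least 2 cell lines for feature selection")
    if len(y) != len(sites):
        raise ValueError("class_labels must align with the site matrix rows")

    # SU values are rounded to 9 decimals before every comparison: ranking
    # ties and >=-dominance boundaries frequently fall on mathematically
    # equal values that differ only in float rounding
    relevance = {c: round(symmetrical_uncertainty(sites[c].to_numpy(), y), 9)
                 for c in sites.columns}
    candidates = [c for c in sites.columns if relevance[c] >= delta]
    candidates.sort(key=lambda c: (-relevance[c], str(c)))

    kept: list = []
    for cand in candidates:
        dominated = False
        for k in kept:
            if round(symmetrical_uncertainty(sites[k].to_numpy(),
                                             sites[cand].to_numpy()), 9) >= relevance[cand]:
                dominated = True
                break
        if not dominated:
            kept.append(cand)
    if not kept:
        logger.warning("fcbf_select: no site reached delta=%.2f; empty selection", delta)
    return FcbfResult(selected=kept, relevance=relevance)


# ---------------------------------------------------------------------------
# Cell descriptor assembly
# ---------------------------------------------------------------------------


def build_cell_descriptor(cell, mutations: pd.DataFrame, beta: pd.DataFrame,
                          selected: FcbfResult, normal: bool = False) -> np.ndarray:
    """Concatenated [mutation block, selected beta block] for one cell line.

    A ``normal`` (non-cancer) cell line carries no mutation annotation and
    gets an all-zero mutation block; its beta values must still be present
    for every FCBF-selected site.
    """
    if normal:
        mut = np.zeros(mutations.shape[1])
    else:
        if cell not in mutations.index:
            raise KeyError(f"cell line {cell!r} not found in the mutation matrix")
        mut = mutations.loc[cell].to_numpy(dtype=float)
    if cell not in beta.index:
        raise KeyError(f"cell line {cell!r} not found in the beta matrix")
    missing = [s for s in selected.selected if s not in beta.columns]
    if missing:
        raise KeyError(f"cell line {cell!r} lacks beta values for selected "
                       f"site(s): {missing[:10]}")
    sel = beta.loc[cell, selected.selected].to_numpy(dtype=float) if selected.selected \
        else np.zeros(0)
    return np.concatenate([mut, sel])
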