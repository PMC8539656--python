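"""Seeded synthetic fixtures with the statistical structure the pipeline assumes.

Emulates, at desk scale, the inputs of a LINCS-style chemogenomic study:

* a long-format perturbation table (drug, gene, cell line, dose, time,
  Z-score) with a planted drug–gene regulation signal,
* a SMILES table per drug,
* a gene → GO-term annotation map,
* a binary cell-line × mutation-marker matrix,
* methylated/unmethylated probe-intensity matrices whose beta values carry
  a histology-correlated signal (so correlation-filter feature selection
  has something to find),
* a histology label per cell line,
* a pro-/anti-longevity gene label table.

Everything is driven by a single integer seed through independent child
streams, so any piece of the world (e.g. the planted ground truth) can be
re-derived from the config alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticConfig",
    "SyntheticWorld",
    "gen_world",
    "planted_truth",
    "load_world",
    "SMILES_POOL",
    "drug_smiles",
]

# ---------------------------------------------------------------------------
# SMILES pool
# ---------------------------------------------------------------------------

#: Hard-coded pool of valid, diverse drug-like SMILES (well-known small
#: molecules, stereochemistry stripped).  Cycled for the first 50 drugs;
#: beyond that, an enumerated homologous series of O-alkyl phenylalanine
#: analogues provides unlimited further valid structures.
SMILES_POOL: tuple[str, ...] = (
    "CC(=O)Oc1ccccc1C(=O)O",                     # aspirin
    "Cn1cnc2c1c(=O)n(C)c(=O)n2C",                # caffeine
    "CC(C)Cc1ccc(C(C)C(=O)O)cc1",                # ibuprofen
    "CC(=O)Nc1ccc(O)cc1",                        # paracetamol
    "COc1ccc2cc(C(C)C(=O)O)ccc2c1",              # naproxen
    "CN1CCCC1c1cccnc1",                          # nicotine
    "CCOC(=O)c1ccc(N)cc1",                       # benzocaine
    "CCN(CC)CCOC(=O)c1ccc(N)cc1",                # procaine
    "CCN(CC)CC(=O)Nc1c(C)cccc1C",                # lidocaine
    "CC(=O)CC(c1ccccc1)c1c(O)c2ccccc2oc1=O",     # warfarin
    "CN1C(=O)CN=C(c2ccccc2)c2cc(Cl)ccc21",       # diazepam
    "CN(C)C(=N)NC(=N)N",                         # metformin
    "CC(C)(C)NCC(O)c1ccc(O)c(CO)c1",             # salbutamol
    "CC(C)NCC(O)COc1ccc(CC(N)=O)cc1",            # atenolol
    "CC(C)NCC(O)COc1cccc2ccccc12",               # propranolol
    "CN(C)CCCN1c2ccccc2Sc2ccc(Cl)cc21",          # chlorpromazine
    "O=C(CCCN1CCC(O)(c2ccc(Cl)cc2)CC1)c1ccc(F)cc1",  # haloperidol
    "CNCCC(Oc1ccc(C(F)(F)F)cc1)c1ccccc1",        # fluoxetine
    "CNC1CCC(c2ccc(Cl)c(Cl)c2)c2ccccc21",        # sertraline
    "CN(C)CCCN1c2ccccc2CCc2ccccc21",             # imipramine
    "CN(C)CCC=C1c2ccccc2CCc2ccccc21",            # amitriptyline
    "Cc1nc[nH]c1CSCCNC(=NC)NC#N",                # cimetidine
    "CNC(=C[N+](=O)[O-])NCCSCc1ccc(CN(C)C)o1",   # ranitidine
    "COc1ccc2[nH]c(S(=O)Cc3ncc(C)c(OC)c3C)nc2c1",    # omeprazole
    "Cc1cc(NS(=O)(=O)c2ccc(N)cc2)no1",           # sulfamethoxazole
    "COc1cc(Cc2cnc(N)nc2N)cc(OC)c1OC",           # trimethoprim
    "O=C1NC(=O)C(c2ccccc2)(c2ccccc2)N1",         # phenytoin
    "NC(=O)N1c2ccccc2C=Cc2ccccc21",              # carbamazepine
    "CCCC(CCC)C(=O)O",                           # valproic acid
    "NCC1(CC(=O)O)CCCCC1",                       # gabapentin
    "CC1(C)SC2C(NC(=O)Cc3ccccc3)C(=O)N2C1C(=O)O",    # penicillin G
    "O=[N+]([O-])c1ccc(C(O)C(CO)NC(=O)C(Cl)Cl)cc1",  # chloramphenicol
    "Cc1ncc([N+](=O)[O-])n1CCO",                 # metronidazole
    "O=C(O)c1cn(C2CC2)c2cc(N3CCNCC3)c(F)cc2c1=O",    # ciprofloxacin
    "NNC(=O)c1ccncc1",                           # isoniazid
    "CCC(CO)NCCNC(CC)CO",                        # ethambutol
    "Nc1ccc(S(=O)(=O)c2ccc(N)cc2)cc1",           # dapsone
    "NS(=O)(=O)c1cc2c(cc1Cl)NCNS2(=O)=O",        # hydrochlorothiazide
    "NS(=O)(=O)c1cc(C(=O)O)c(NCc2ccco2)cc1Cl",   # furosemide
    "CC(CS)C(=O)N1CCCC1C(=O)O",                  # captopril
    "CCOC(=O)C(CCc1ccccc1)NC(C)C(=O)N1CCCC1C(=O)O",  # enalapril
    "COC(=O)C1=C(C)NC(C)=C(C(=O)OC)C1c1ccccc1[N+](=O)[O-]",  # nifedipine
    "COc1ccc(CCN(C)CCCC(C#N)(C(C)C)c2ccc(OC)c(OC)c2)cc1OC",  # verapamil
    "Cn1c(=O)c2[nH]cnc2n(C)c1=O",                # theophylline
    "CCN(CC)CCCC(C)Nc1ccnc2cc(Cl)ccc12",         # chloroquine
    "NCCc1ccc(O)c(O)c1",                         # dopamine
    "NCCc1c[nH]c2ccc(O)cc12",                    # serotonin
    "COc1ccc2[nH]cc(CCNC(C)=O)c2c1",             # melatonin
    "CNCC(O)c1ccc(O)c(O)c1",                     # epinephrine
    "NC(Cc1c[nH]c2ccccc12)C(=O)O",               # tryptophan
)


def drug_smiles(index: int) -> str:
    """SMILES for the ``index``-th synthetic drug.

    The first ``len(SMILES_POOL)`` drugs take pool entries verbatim;
    later drugs are an enumerated homologous series (growing O-alkyl
    chain on a phenylalanine scaffold), guaranteeing parseable,
    pairwise-distinct structures for any count.
    """
    if index < len(SMILES_POOL):
        return SMILES_POOL[index]
    k = index - len(SMILES_POOL) + 1
    return "C" * k + "Oc1ccc(CC(N)C(=O)O)cc1"


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------


def _floor_frac(frac: float, n: int) -> int:
    # floor(frac*n) with an epsilon so exact rationals (397/889 of 889)
    # survive binary floating point.
    return int(math.floor(frac * n + 1e-9))


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one synthetic world.

    Defaults mirror the real study's label proportions (397 pro- and 492
    anti-longevity genes out of 889) at a desk-scale world size; the
    off-unit/off-time fractions exercise the dose-unit and treatment-time
    record filters downstream.
    """

    n_drugs: int = 30
    n_genes: int = 889
    n_cells: int = 8
    n_go_terms: int = 120
    n_mutation_markers: int = 40
    n_cpg_sites: int = 200
    n_histology_classes: int = 3
    frac_pro: float = 397 / 889
    frac_anti: float = 492 / 889
    planted_pairs: int = 20
    effect_size: float = 3.0
    seed: int = 0
    # --- generator plumbing (not part of the study design) -------------
    n_background_pairs: int = 600   # non-planted (drug, gene) pairs with records
    replicate_frac: float = 0.2     # fraction of (pair, cell) combos given a 2nd dose
    frac_offunit: float = 0.1       # records re-dosed in nM (filtered downstream)
    frac_offtime: float = 0.1       # records re-timed to 6 h (filtered downstream)
    n_informative_cpg: int | None = None  # default: n_cpg_sites // 5

    def __post_init__(self) -> None:
        counts = (
            self.n_drugs, self.n_genes, self.n_cells, self.n_go_terms,
            self.n_mutation_markers, self.n_cpg_sites,
            self.n_histology_classes, self.planted_pairs,
        )
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        if self.frac_pro < 0 or self.frac_anti < 0 or self.frac_pro + self.frac_anti > 1 + 1e-12:
            raise ValueError("need frac_pro, frac_anti >= 0 and frac_pro + frac_anti <= 1")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")

    @property
    def informative_cpg(self) -> int:
        n = self.n_cpg_sites // 5 if self.n_informative_cpg is None else self.n_informative_cpg
        return min(n, self.n_cpg_sites)

    # id vocabularies ----------------------------------------------------
    def drug_ids(self) -> list[str]:
        return [f"DRUG{i:04d}" for i in range(self.n_drugs)]

    def gene_symbols(self) -> list[str]:
        return [f"G{i:04d}" for i in range(self.n_genes)]

    def cell_lines(self) -> list[str]:
        return [f"CELL{i:02d}" for i in range(self.n_cells)]

    def go_terms(self) -> list[str]:
        return [f"GO:{7000000 + i:07d}" for i in range(self.n_go_terms)]

    def markers(self) -> list[str]:
        return [f"MUT{i:03d}" for i in range(self.n_mutation_markers)]

    def cpg_sites(self) -> list[str]:
        return [f"cg{i:06d}" for i in range(self.n_cpg_sites)]


@dataclass
class SyntheticWorld:
    """The generated bundle: one DataFrame per pipeline input."""

    config: SyntheticConfig
    perturbations: pd.DataFrame   # drug_id, gene_symbol, cell_line, dose_value, dose_unit, time_h, z_score
    smiles: pd.DataFrame          # drug_id, smiles
    go_annotations: pd.DataFrame  # gene_symbol, go_term (long two-column)
    mutations: pd.DataFrame       # cell_line x marker, binary
    intensities_meth: pd.DataFrame    # cell_line x cpg site, nonnegative
    intensities_unmeth: pd.DataFrame  # cell_line x cpg site, nonnegative
    histology: pd.DataFrame       # cell_line, histology
    longevity: pd.DataFrame       # gene_symbol, effect in {pro, anti}

    def write(self, outdir: str | Path) -> None:
        """Write the bundle as the plain-text files downstream stages read."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.perturbations.to_csv(outdir / "perturbations.tsv", sep="\t", index=False)
        self.smiles.to_csv(outdir / "smiles.csv", index=False)
        self.go_annotations.to_csv(outdir / "go_annotations.tsv", sep="\t", index=False)
        self.mutations.to_csv(outdir / "mutations.csv", index_label="cell_line")
        self.intensities_meth.to_csv(outdir / "intensities_meth.csv", index_label="cell_line")
        self.intensities_unmeth.to_csv(outdir / "intensities_unmeth.csv", index_label="cell_line")
        self.histology.to_csv(outdir / "histology.csv", index=False)
        self.longevity.to_csv(outdir / "longevity.csv", index=False)


def load_world(indir: str | Path, config: SyntheticConfig | None = None) -> SyntheticWorld:
    """Read a bundle previously written by :meth:`SyntheticWorld.write`
    (or user-supplied files in the same layout)."""
    indir = Path(indir)
    return SyntheticWorld(
        config=config if config is not None else SyntheticConfig(),
        perturbations=pd.read_csv(indir / "perturbations.tsv", sep="\t"),
        smiles=pd.read_csv(indir / "smiles.csv"),
        go_annotations=pd.read_csv(indir / "go_annotations.tsv", sep="\t"),
        mutations=pd.read_csv(indir / "mutations.csv", index_col="cell_line"),
        intensities_meth=pd.read_csv(indir / "intensities_meth.csv", index_col="cell_line"),
        intensities_unmeth=pd.read_csv(indir / "intensities_unmeth.csv", index_col="cell_line"),
        histology=pd.read_csv(indir / "histology.csv"),
        longevity=pd.read_csv(indir / "longevity.csv"),
    )


# ---------------------------------------------------------------------------
# Seed streams
# ---------------------------------------------------------------------------

# Child-stream indices; planted_truth() regenerates stream _S_PLANT alone.
_S_PLANT, _S_PERT, _S_GO, _S_MUT, _S_METH, _S_LABEL = range(6)


def _streams(config: SyntheticConfig) -> list[np.random.Generator]:
    children = np.random.SeedSequence(config.seed).spawn(6)
    return [np.random.default_rng(s) for s in children]


# ---------------------------------------------------------------------------
# Planted truth
# ---------------------------------------------------------------------------


def _longevity_labels(config: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    genes = np.array(config.gene_symbols())
    n_pro = _floor_frac(config.frac_pro, config.n_genes)
    n_anti = _floor_frac(config.frac_anti, config.n_genes)
    perm = rng.permutation(config.n_genes)
    effect = np.full(config.n_genes, "", dtype=object)
    effect[perm[:n_pro]] = "pro"
    effect[perm[n_pro:n_pro + n_anti]] = "anti"
    keep = effect != ""
    return pd.DataFrame({"gene_symbol": genes[keep], "effect": effect[keep]})


def planted_truth(config: SyntheticConfig) -> pd.DataFrame:
    """Ground-truth planted (drug, gene, direction) triples for ``config``.

    Derived from the config's seed alone, so it matches the world
    :func:`gen_world` builds for the same config.  Planted "up" pairs
    target pro-longevity genes and planted "down" pairs anti-longevity
    genes (when those label sets are nonempty), so that planted drugs
    carry the desired-direction signal the repurposing ranking looks for.
    """
    streams = _streams(config)
    rng = streams[_S_PLANT]
    longevity = _longevity_labels(config, streams[_S_LABEL])

    n = config.planted_pairs
    if n == 0 or config.n_drugs == 0 or config.n_genes == 0:
        return pd.DataFrame(columns=["drug_id", "gene_symbol", "direction"])

    drugs = config.drug_ids()
    pro = list(longevity.loc[longevity["effect"] == "pro", "gene_symbol"])
    anti = list(longevity.loc[longevity["effect"] == "anti", "gene_symbol"])
    all_genes = config.gene_symbols()

    rows: list[tuple[str, str, str]] = []
    used: set[tuple[str, str]] = set()
    directions = np.where(np.arange(n) % 2 == 0, "up", "down")
    # Concentrate planted pairs on few drugs so planted drugs accumulate
    # many desired interactions (the ranking signal).
    n_planted_drugs = max(1, min(config.n_drugs, int(math.ceil(n / 4))))
    planted_drugs = [drugs[i] for i in rng.choice(config.n_drugs, size=n_planted_drugs, replace=False)]
    for i in range(n):
        direction = str(directions[i])
        gene_pool = pro if (direction == "up" and pro) else anti if (direction == "down" and anti) else all_genes
        for _ in range(1000):
            d = planted_drugs[int(rng.integers(len(planted_drugs)))]
            g = gene_pool[int(rng.integers(len(gene_pool)))]
            if (d, g) not in used:
                used.add((d, g))
                rows.append((d, g, direction))
                break
        else:  # pool exhausted: fall back to any gene
            for g in all_genes:
                d = planted_drugs[int(rng.integers(len(planted_drugs)))]
                if (d, g) not in used:
                    used.add((d, g))
                    rows.append((d, g, direction))
                    break
    return pd.DataFrame(rows, columns=["drug_id", "gene_symbol", "direction"])


# ---------------------------------------------------------------------------
# World generation
# ---------------------------------------------------------------------------


def _gen_perturbations(config: SyntheticConfig, rng: np.random.Generator,
                       planted: pd.DataFrame) -> pd.DataFrame:
    cols = ["drug_id", "gene_symbol", "cell_line", "dose_value", "dose_unit", "time_h", "z_score"]
    if config.n_drugs == 0 or config.n_genes == 0 or config.n_cells == 0:
        return pd.DataFrame(columns=cols)

    drugs = config.drug_ids()
    genes = config.gene_symbols()
    cells = config.cell_lines()

    planted_set = {(d, g): direc for d, g, direc in planted.itertuples(index=False)}
    pairs: list[tuple[str, str]] = list(planted_set)
    seen = set(planted_set)
    target = len(planted_set) + config.n_background_pairs
    while len(pairs) < target:
        d = drugs[int(rng.integers(config.n_drugs))]
        g = genes[int(rng.integers(config.n_genes))]
        if (d, g) not in seen:
            seen.add((d, g))
            pairs.append((d, g))

    rows_d, rows_g, rows_c = [], [], []
    for d, g in pairs:
        for c in cells:
            rows_d.append(d)
            rows_g.append(g)
            rows_c.append(c)
    n_rows = len(rows_d)

    shift = np.zeros(n_rows)
    for i, (d, g) in enumerate(zip(rows_d, rows_g)):
        direc = planted_set.get((d, g))
        if direc == "up":
            shift[i] = config.effect_size
        elif direc == "down":
            shift[i] = -config.effect_size

    z = rng.standard_normal(n_rows) + shift
    dose = np.round(10.0 ** rng.uniform(-1, 1, n_rows), 3)  # 0.1–10 µM
    unit = np.full(n_rows, "µM", dtype=object)
    time_h = np.full(n_rows, 24.0)

    df = pd.DataFrame({
        "drug_id": rows_d, "gene_symbol": rows_g, "cell_line": rows_c,
        "dose_value": dose, "dose_unit": unit, "time_h": time_h, "z_score": z,
    })

    # Dose replicates: a second record at a different dose for a fraction
    # of rows (exercises downstream deduplication).
    n_rep = int(round(config.replicate_frac * n_rows))
    if n_rep:
        rep_idx = rng.choice(n_rows, size=n_rep, replace=False)
        rep = df.iloc[rep_idx].copy()
        rep["dose_value"] = np.round(rep["dose_value"] * 3.16, 3)
        rep["z_score"] = rep["z_score"] + 0.3 * rng.standard_normal(n_rep)
        df = pd.concat([df, rep], ignore_index=True)

    # Off-condition noise: these records must be removed by the 24 h / µM
    # filters, so they get no planted information beyond what they carry.
    n_all = len(df)
    off_unit = rng.random(n_all) < config.frac_offunit
    off_time = rng.random(n_all) < config.frac_offtime
    df.loc[off_unit, "dose_unit"] = "nM"
    df.loc[off_unit, "dose_value"] = df.loc[off_unit, "dose_value"] * 1000
    df.loc[off_time, "time_h"] = 6.0
    return df[cols]


def _gen_go(config: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    if config.n_go_terms == 0 or config.n_genes == 0:
        return pd.DataFrame(columns=["gene_symbol", "go_term"])
    genes = np.array(config.gene_symbols())
    rows = []
    for term in config.go_terms():
        # term sizes span the min-genes filter boundary: 1 .. ~6% of genes
        size = int(rng.integers(1, max(2, config.n_genes // 16)))
        members = rng.choice(config.n_genes, size=min(size, config.n_genes), replace=False)
        for m in members:
            rows.append((genes[m], term))
    df = pd.DataFrame(rows, columns=["gene_symbol", "go_term"])
    return df.sort_values(["gene_symbol", "go_term"], ignore_index=True)


def _gen_mutations(config: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    mat = (rng.random((config.n_cells, config.n_mutation_markers)) < 0.25).astype(int)
    return pd.DataFrame(mat, index=pd.Index(config.cell_lines(), name="cell_line"),
                        columns=config.markers())


def _gen_methylation(config: SyntheticConfig, rng: np.random.Generator
                     ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    cells = config.cell_lines()
    sites = config.cpg_sites()
    n_c, n_s = config.n_cells, config.n_cpg_sites
    n_classes = max(1, config.n_histology_classes)
    hist = np.array([f"HIST{i % n_classes}" for i in range(n_c)])
    hist = hist[rng.permutation(n_c)] if n_c else hist

    meth = np.zeros((n_c, n_s))
    unmeth = np.zeros((n_c, n_s))
    n_inf = config.informative_cpg
    for j in range(n_s):
        if j < n_inf:
            # class-dependent target beta level; each site gets its own
            # class-to-level mapping and per-cell jitter, so informative
            # sites correlate with histology without being exact copies
            # of one another
            cls = np.array([int(h[4:]) for h in hist], dtype=int)
            perm = rng.permutation(n_classes)
            b = (perm[cls] + 0.5) / n_classes if n_c else np.zeros(0)
            b = np.clip(b + rng.normal(0.0, 0.1, n_c), 0.02, 0.98)
        else:
            b = np.full(n_c, rng.uniform(0.2, 0.8))
        total = rng.gamma(shape=40.0, scale=50.0, size=n_c)  # ~2000 counts
        meth[:, j] = b * total * rng.uniform(0.95, 1.05, n_c)
        unmeth[:, j] = (1 - b) * total * rng.uniform(0.95, 1.05, n_c)

    idx = pd.Index(cells, name="cell_line")
    return (pd.DataFrame(meth, index=idx, columns=sites),
            pd.DataFrame(unmeth, index=idx, columns=sites),
            pd.DataFrame({"cell_line": cells, "histology": hist}))


def gen_world(config: SyntheticConfig) -> SyntheticWorld:
    """Generate the full synthetic input bundle for ``config``.

    Deterministic: the same config (including seed) yields byte-identical
    tables.  Zero-size requests produce empty tables rather than errors.
    """
    streams = _streams(config)
    planted = planted_truth(config)
    longevity = _longevity_labels(config, streams[_S_LABEL])
    perturbations = _gen_perturbations(config, streams[_S_PERT], planted)
    smiles = pd.DataFrame({
        "drug_id": config.drug_ids(),
        "smiles": [drug_smiles(i) for i in range(config.n_drugs)],
    })
    go = _gen_go(config, streams[_S_GO])
    mutations = _gen_mutations(config, streams[_S_MUT])
    meth, unmeth, histology = _gen_methylation(config, streams[_S_METH])
    return SyntheticWorld(
        config=config,
        perturbations=perturbations,
        smiles=smiles,
        go_annotations=go,
        mutations=mutations,
        intensities_meth=meth,
        intensities_unmeth=unmeth,
        histology=histology,
        longevity=longevity,
    )
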