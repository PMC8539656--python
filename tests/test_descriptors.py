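"""Descriptor blocks: GO one-hot, fingerprints, beta values, SU, FCBF."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gerochem.descriptors import (FcbfResult, FingerprintError,
                                  build_cell_descriptor, build_go_matrix,
                                  compute_beta, discretize_beta, fcbf_select,
                                  fingerprint, fingerprint_table,
                                  symmetrical_uncertainty)

# ---------------------------------------------------------------------------
# GO one-hot
# ---------------------------------------------------------------------------

TOY_ANN = {
    "G1": {"T1", "T2", "T3"},
    "G2": {"T1", "T2"},
    "G3": {"T1", "T4"},
    "G4": {"T2", "T5"},
    "G5": set(),
}


def test_go_matrix_matches_double_loop_oracle():
    genes = ["G1", "G2", "G3", "G4", "G5"]
    mat = build_go_matrix(TOY_ANN, genes, min_genes=2)
    # oracle: brute-force membership table over terms annotating >= 2 genes
    all_terms = sorted({t for s in TOY_ANN.values() for t in s})
    vocab = [t for t in all_terms
             if sum(t in TOY_ANN[g] for g in genes) >= 2]
    assert list(mat.columns) == vocab
    for g in genes:
        for t in vocab:
            assert mat.loc[g, t] == int(t in TOY_ANN[g])


def test_terms_below_min_genes_dropped():
    mat = build_go_matrix(TOY_ANN, ["G1", "G2", "G3", "G4"], min_genes=3)
    # only T1 (3 genes) and T2 (3 genes) survive; T3/T4/T5 annotate < 3
    assert list(mat.columns) == ["T1", "T2"]


def test_unannotated_gene_gets_zero_row():
    mat = build_go_matrix(TOY_ANN, ["G1", "G5"], min_genes=1)
    assert mat.loc["G5"].sum() == 0


def test_column_sums_at_least_min_genes(small_world):
    from gerochem.descriptors import annotation_map
    ann = annotation_map(small_world.go_annotations)
    genes = sorted(set(small_world.go_annotations["gene_symbol"]))
    mat = build_go_matrix(ann, genes, min_genes=3)
    assert (mat.sum(axis=0) >= 3).all()


# ---------------------------------------------------------------------------
# Morgan fingerprints
# ---------------------------------------------------------------------------


def test_fingerprint_length_and_binary():
    fp = fingerprint("CC(=O)Oc1ccccc1C(=O)O")
    assert fp.shape == (2048,)
    assert set(np.unique(fp)) <= {0, 1}


def test_kekulized_and_aromatic_benzene_match():
    assert np.array_equal(fingerprint("C1=CC=CC=C1"), fingerprint("c1ccccc1"))


def test_methane_bit_count_frozen_reference():
    # reference Morgan computation (radius 2, 2048 bits) gives exactly one
    # set bit for methane, at index 1264; aspirin sets 24 bits
    fp = fingerprint("C")
    assert fp.sum() == 1
    assert fp[1264] == 1
    assert fingerprint("CC(=O)Oc1ccccc1C(=O)O").sum() == 24


def test_unparseable_smiles_raises_and_is_excluded():
    with pytest.raises(FingerprintError):
        fingerprint("not-a-molecule(((")
    table = pd.DataFrame({"drug_id": ["A", "B"], "smiles": ["CCO", "))("]})
    mat, failed = fingerprint_table(table, n_bits=64)
    assert failed == ["B"]
    assert list(mat.index) == ["A"]


# ---------------------------------------------------------------------------
# beta values
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("meth,unmeth,alpha,expected", [
    (0.0, 500.0, 100.0, 0.0),          # zero numerator
    (-5.0, -5.0, 100.0, 0.0),          # both channels clamped at 0
    (300.0, 700.0, 100.0, 300.0 / 1100.0),
    (1000.0, 0.0, 100.0, 1000.0 / 1100.0),
])
def test_beta_direct_values(meth, unmeth, alpha, expected):
    assert compute_beta(meth, unmeth, alpha) == pytest.approx(expected)


def test_beta_rejects_nonpositive_alpha():
    with pytest.raises(ValueError):
        compute_beta(1.0, 1.0, 0.0)


@settings(max_examples=100, deadline=None)
@given(st.floats(-100, 1e4), st.floats(-100, 1e4),
       st.floats(0.1, 1e3), st.floats(0.1, 200))
def test_beta_bounds_and_monotonicity(meth, unmeth, alpha, bump):
    b = compute_beta(meth, unmeth, alpha)
    assert 0.0 <= b < 1.0
    assert compute_beta(meth + bump, unmeth, alpha) >= b        # inc. in meth
    assert compute_beta(meth, unmeth + bump, alpha) <= b        # dec. in unmeth
    assert compute_beta(meth, unmeth, alpha + bump) <= b        # dec. in alpha


def test_discretize_beta_bins():
    df = pd.DataFrame([[0.0, 0.32, 0.34, 0.99, 1.0]], index=["c"],
                      columns=list("abcde"))
    codes = discretize_beta(df, n_bins=3)
    assert codes.to_numpy().tolist() == [[0, 0, 1, 2, 2]]


# ---------------------------------------------------------------------------
# symmetrical uncertainty
# ---------------------------------------------------------------------------


def _su_oracle(x, y):
    """Contingency-table computation of 2 I(x;y) / (H(x)+H(y))."""
    import collections
    import math
    n = len(x)
    px = collections.Counter(x)
    py = collections.Counter(y)
    pxy = collections.Counter(zip(x, y))
    hx = -sum(c / n * math.log2(c / n) for c in px.values())
    hy = -sum(c / n * math.log2(c / n) for c in py.values())
    if hx == 0 or hy == 0:
        return 0.0
    mi = sum(c / n * math.log2((c / n) / (px[a] / n * py[b] / n))
             for (a, b), c in pxy.items())
    return 2 * mi / (hx + hy)


def test_su_perfect_dependence_and_constant():
    x = np.array([0, 1, 0, 1, 1, 0])
    assert symmetrical_uncertainty(x, x) == pytest.approx(1.0)
    assert symmetrical_uncertainty(np.zeros(6), x) == 0.0
    # a relabeling of x is still perfectly dependent
    assert symmetrical_uncertainty(x, 1 - x) == pytest.approx(1.0)


def test_su_eight_element_toy_matches_oracle():
    x = [0, 0, 1, 1, 0, 1, 0, 1]
    y = [0, 0, 1, 0, 0, 1, 1, 1]
    assert symmetrical_uncertainty(x, y) == pytest.approx(_su_oracle(x, y))


@settings(max_examples=60, deadline=None)
@given(st.lists(st.integers(0, 3), min_size=2, max_size=30),
       st.integers(0, 2 ** 31 - 1))
def test_su_symmetric_and_matches_oracle(xs, seed):
    rng = np.random.default_rng(seed)
    ys = rng.integers(0, 3, size=len(xs))
    su_xy = symmetrical_uncertainty(xs, ys)
    su_yx = symmetrical_uncertainty(ys, xs)
    assert su_xy == pytest.approx(su_yx)
    assert su_xy == pytest.approx(_su_oracle(tuple(xs), tuple(ys)), abs=1e-9)
    assert 0.0 <= su_xy <= 1.0


# ---------------------------------------------------------------------------
# FCBF
# ---------------------------------------------------------------------------


def _fcbf_oracle(sites: pd.DataFrame, y, delta):
    """Independent enumeration of the ranked redundancy scan."""
    # SU rounded to 9 decimals as in the implementation contract: tie and
    # dominance boundaries sit on mathematically equal values whose two
    # float computation routes differ in the last bits
    rel = {c: round(_su_oracle(tuple(sites[c]), tuple(y)), 9) for c in sites.columns}
    order = sorted((c for c in sites.columns if rel[c] >= delta),
                   key=lambda c: (-rel[c], str(c)))
    kept = []
    for cand in order:
        if not any(round(_su_oracle(tuple(sites[k]), tuple(sites[cand])), 9) >= rel[cand]
                   for k in kept):
            kept.append(cand)
    return kept


def test_fcbf_site_equal_to_class_selected_first():
    y = np.array([0, 1, 2, 0, 1, 2, 0, 1, 2, 0, 1, 2])
    sites = pd.DataFrame({"exact": y, "noise": np.arange(12) % 2})
    res = fcbf_select(sites, y, delta=0.6)
    assert res.selected[0] == "exact"
    assert res.relevance["exact"] == pytest.approx(1.0)


def test_fcbf_duplicate_site_removed_as_redundant():
    y = np.array([0, 1, 0, 1, 1, 0, 1, 0])
    sites = pd.DataFrame({"a": y, "b": y})
    res = fcbf_select(sites, y, delta=0.6)
    assert res.selected == ["a"]  # rank tie broken lexically; copy dominated


def test_fcbf_empty_selection_when_no_site_relevant():
    rng = np.random.default_rng(0)
    y = rng.integers(0, 2, 40)
    sites = pd.DataFrame({"r1": rng.integers(0, 2, 40), "r2": rng.integers(0, 2, 40)})
    res = fcbf_select(sites, y, delta=0.99)
    assert res.selected == []


@settings(max_examples=40, deadline=None)
@given(st.integers(0, 2 ** 31 - 1))
def test_fcbf_matches_bruteforce_enumeration_on_toys(seed):
    rng = np.random.default_rng(seed)
    n_cells, n_sites = 12, 6
    y = rng.integers(0, 3, n_cells)
    cols = {}
    for j in range(n_sites):
        if j % 3 == 0:     # noisy copy of the class
            v = y.copy()
            flip = rng.random(n_cells) < 0.2
            v[flip] = rng.integers(0, 3, flip.sum())
            cols[f"s{j}"] = v
        else:
            cols[f"s{j}"] = rng.integers(0, 3, n_cells)
    sites = pd.DataFrame(cols)
    res = fcbf_select(sites, y, delta=0.3)
    assert res.selected == _fcbf_oracle(sites, y, 0.3)
    rels = res.selected_relevance()
    assert all(r >= 0.3 for r in rels)
    assert rels == sorted(rels, reverse=True)


def test_fcbf_invariant_to_site_order():
    rng = np.random.default_rng(4)
    y = rng.integers(0, 3, 12)
    sites = pd.DataFrame({f"s{j}": rng.integers(0, 3, 12) for j in range(6)})
    a = fcbf_select(sites, y, delta=0.2).selected
    b = fcbf_select(sites[list(reversed(sites.columns))], y, delta=0.2).selected
    assert a == b


# ---------------------------------------------------------------------------
# cell descriptor assembly
# ---------------------------------------------------------------------------


def _toy_cell_matrices():
    mut = pd.DataFrame([[1, 0, 1], [0, 0, 0]], index=["C1", "C2"],
                       columns=["m1", "m2", "m3"])
    beta = pd.DataFrame([[0.1, 0.5, 0.9], [0.2, 0.6, 0.8]],
                        index=["C1", "C2"], columns=["cg1", "cg2", "cg3"])
    sel = FcbfResult(selected=["cg3", "cg1"], relevance={"cg1": 0.7, "cg3": 0.8})
    return mut, beta, sel


def test_cell_descriptor_manual_concatenation():
    mut, beta, sel = _toy_cell_matrices()
    vec = build_cell_descriptor("C1", mut, beta, sel)
    assert vec.tolist() == [1, 0, 1, 0.9, 0.1]  # mutation block then beta in selection order
    assert np.array_equal(vec, build_cell_descriptor("C1", mut, beta, sel))


def test_normal_cell_gets_zero_mutation_block():
    mut, beta, sel = _toy_cell_matrices()
    beta.loc["NORMAL"] = [0.3, 0.4, 0.5]
    vec = build_cell_descriptor("NORMAL", mut, beta, sel, normal=True)
    assert vec.tolist() == [0, 0, 0, 0.5, 0.3]


def test_unknown_cell_error_names_the_cell():
    mut, beta, sel = _toy_cell_matrices()
    with pytest.raises(KeyError, match="C9"):
        build_cell_descriptor("C9", mut, beta, sel)
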