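"""Poisson distances, neighbor joining, bootstrap supports."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tralocus.phylo import (
    DistanceMatrix,
    UndefinedDistanceError,
    bootstrap_support,
    nj_tree,
    poisson_distance,
)

aa = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY-", min_size=5, max_size=40)


def test_poisson_closed_form_values():
    assert poisson_distance("MKLV", "MKLV") == 0.0
    d = poisson_distance("A" * 10, "A" * 5 + "C" * 5)  # p = 0.5
    assert abs(d - (-math.log(0.5))) < 1e-12


def test_pairwise_deletion_matches_columnwise_oracle():
    a = "MK-LVQ-RS"
    b = "MKALV--RT"
    compared = sum(1 for x, y in zip(a, b) if x != "-" and y != "-")
    diffs = sum(1 for x, y in zip(a, b) if x != "-" and y != "-" and x != y)
    assert compared == 6 and diffs == 1
    assert abs(poisson_distance(a, b) + math.log(1 - diffs / compared)) < 1e-12


def test_poisson_error_cases():
    with pytest.raises(UndefinedDistanceError):
        poisson_distance("AAAA", "CCCC")
    with pytest.raises(ValueError):
        poisson_distance("----", "AAAA")
    with pytest.raises(ValueError):
        poisson_distance("AA", "AAA")


@settings(max_examples=40, derandomize=True, deadline=None)
@given(aa, aa)
def test_poisson_symmetry_and_zero_iff_identical(a, b):
    n = min(len(a), len(b))
    a, b = a[:n], b[:n]
    try:
        d_ab = poisson_distance(a, b)
        d_ba = poisson_distance(b, a)
    except (ValueError, UndefinedDistanceError):
        return
    assert d_ab == d_ba >= 0.0
    comparable = [(x, y) for x, y in zip(a, b) if x != "-" and y != "-"]
    assert (d_ab == 0.0) == all(x == y for x, y in comparable)


def test_nj_three_taxa_closed_form():
    ids = ["A", "B", "C"]
    m = np.array([[0.0, 3.0, 5.0], [3.0, 0.0, 6.0], [5.0, 6.0, 0.0]])
    tree = nj_tree(DistanceMatrix(ids, m))
    lengths = {leaf.name: leaf.length for leaf in tree.leaves()}
    assert abs(lengths["A"] - 1.0) < 1e-12  # (dAB + dAC - dBC)/2
    assert abs(lengths["B"] - 2.0) < 1e-12
    assert abs(lengths["C"] - 4.0) < 1e-12


def test_nj_recovers_additive_four_taxon_tree():
    """((A,B),(C,D)) with known branch lengths is reproduced exactly."""
    ids = ["A", "B", "C", "D"]
    d = {("A", "B"): 3.0, ("A", "C"): 8.0, ("A", "D"): 9.0,
         ("B", "C"): 9.0, ("B", "D"): 10.0, ("C", "D"): 9.0}
    m = np.zeros((4, 4))
    for (x, y), v in d.items():
        i, j = ids.index(x), ids.index(y)
        m[i, j] = m[j, i] = v
    tree = nj_tree(DistanceMatrix(ids, m))
    assert tree.bipartitions() == {frozenset({"A", "B"})}
    lengths = {leaf.name: leaf.length for leaf in tree.leaves()}
    for name, expect in (("A", 1.0), ("B", 2.0), ("C", 4.0), ("D", 5.0)):
        assert abs(lengths[name] - expect) < 1e-9
    internal = [c for c in tree.children if c.children][0]
    assert abs(internal.length - 3.0) < 1e-9


def test_nj_matches_scikit_bio_topology():
    """Independent cross-check of the NJ implementation."""
    skbio = pytest.importorskip("skbio")
    from skbio.tree import nj as sknj

    rng = np.random.default_rng(7)
    x = rng.random((7, 7)) + 1
    x = (x + x.T) / 2
    np.fill_diagonal(x, 0)
    ids = [f"t{i}" for i in range(7)]
    mine = nj_tree(DistanceMatrix(ids, x))
    sk = sknj(skbio.DistanceMatrix(x, ids))
    leaves = set(ids)

    def norm(bps):
        return {min(s, frozenset(leaves - s), key=lambda f: (len(f), sorted(f)))
                for s in bps}

    sk_bps = set()
    for node in sk.non_tips(include_self=False):
        s = frozenset(t.name for t in node.tips())
        if 1 < len(s) < len(leaves) - 1:
            sk_bps.add(s)
    assert norm(mine.bipartitions()) == norm(sk_bps)


def test_nj_rejects_undefined_distances():
    m = np.array([[0.0, np.inf], [np.inf, 0.0]])
    with pytest.raises(ValueError):
        nj_tree(DistanceMatrix(["a", "b"], m))


def _two_clade_alignment():
    x = "AAAAAAAAAAAAAAAAAAAA"
    y = "AAAAAAAAAATTTTTTTTTT"  # differs from x at half the sites
    return {
        "X0": x, "X1": x[:19] + "C", "X2": x[:18] + "CC",
        "Y0": y, "Y1": y[:19] + "G", "Y2": y[:18] + "GG",
    }


def test_bootstrap_full_support_on_two_clades():
    tree = bootstrap_support(_two_clade_alignment(), n_reps=200, seed=3)
    supports = {frozenset(c.leaf_names()): c.support
                for c in tree._internal_nodes() if c.support is not None}
    clade_supports = [
        s for names, s in supports.items()
        if {n[0] for n in names} in ({"X"}, {"Y"})
        and len(names) == 3
    ]
    assert clade_supports and all(s == 100.0 for s in clade_supports)


def test_bootstrap_is_deterministic_under_seed():
    t1 = bootstrap_support(_two_clade_alignment(), n_reps=50, seed=9)
    t2 = bootstrap_support(_two_clade_alignment(), n_reps=50, seed=9)
    assert t1.newick(with_support=True) == t2.newick(with_support=True)


def test_supports_within_percent_bounds():
    tree = bootstrap_support(_two_clade_alignment(), n_reps=80, seed=1)
    for node in tree._internal_nodes():
        if node.support is not None:
            assert 0.0 <= node.support <= 100.0
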