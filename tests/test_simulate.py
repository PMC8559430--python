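"""Synthetic locus and repertoire generator: planted truth and determinism."""

from __future__ import annotations

import numpy as np
import pytest

from tralocus._seq import has_stop, translate
from tralocus.genemodel import FGXG_RE, HEPTAMER, NONAMER
from tralocus.repertoire import merge_pairs
from tralocus.simulate import (
    LocusSpec,
    RepertoireSpec,
    simulate_germline_set,
    simulate_locus,
    simulate_repertoire_reads,
)
from tralocus.subgroups import pairwise_identity


def test_no_defect_fractions_gives_all_functional_v_genes():
    """pseudogene/ORF fractions of zero -> every V gene functional."""
    spec = LocusSpec(n_subgroups=3, genes_per_subgroup=(2, 2),
                     pseudogene_fraction=0.0, orf_fraction=0.0, rng_seed=1)
    gl = simulate_germline_set(spec)
    vs = gl.of_type("V")
    assert len(vs) == 6
    assert all(g.functionality == "F" and not g.defects for g in vs)


def test_pseudogene_fraction_is_exact_and_each_p_gene_has_one_defect():
    """Half pseudogenes over 10 genes -> exactly 5 carry a stop/frameshift."""
    spec = LocusSpec(n_subgroups=5, genes_per_subgroup=(2, 2),
                     pseudogene_fraction=0.5, orf_fraction=0.0, rng_seed=2)
    gl = simulate_germline_set(spec)
    vs = gl.of_type("V")
    assert len(vs) == 10
    ps = [g for g in vs if g.functionality == "P"]
    assert len(ps) == 5
    assert all(g.defects in (("stop_codon",), ("frameshift",)) for g in ps)


def test_functional_v_genes_have_intact_structure():
    """F genes: ATG leader, GT..AG intron, stop-free ORF, C23/W41/C104, RS."""
    gl = simulate_germline_set(LocusSpec(rng_seed=3))
    for g in gl.functional("V"):
        lp1 = g.part_seq("L-PART1")
        intron = g.part_seq("V-INTRON")
        region = g.part_seq("V-REGION")
        assert lp1.startswith("ATG")
        assert intron.startswith("GT") and intron.endswith("AG")
        assert not has_stop(g.leader_seq + region)
        aa = translate(region)
        c1, c2, _ = g.meta["cdr"]
        assert aa[22] == "C" and aa[26 + c1 + 2] == "W"
        assert aa[26 + c1 + 17 + c2 + 38] == "C"
        assert g.part_seq("V-HEPTAMER") == HEPTAMER
        assert g.part_seq("V-NONAMER") == NONAMER


def test_functional_traj_have_fgxg_and_trdj_has_fgka():
    gl = simulate_germline_set(LocusSpec(rng_seed=4))
    for g in gl.functional("J", "TRA"):
        assert FGXG_RE.search(translate(g.part_seq("J-REGION")))
    (trdj,) = gl.of_type("J", "TRD")
    aa = translate(trdj.part_seq("J-REGION"))
    assert "FGKA" in aa and not FGXG_RE.search(aa)
    assert trdj.functionality == "F"


def test_identity_separation_on_emitted_sequences():
    """within=0.85 / between=0.60 -> mean within >= 0.80, between <= 0.65."""
    spec = LocusSpec(n_subgroups=4, genes_per_subgroup=(3, 3),
                     within_subgroup_identity=0.85, between_subgroup_identity=0.60,
                     pseudogene_fraction=0.0, orf_fraction=0.0, rng_seed=7)
    gl = simulate_germline_set(spec)
    groups: dict[int, list[str]] = {}
    for g in gl.of_type("V"):
        groups.setdefault(g.subgroup, []).append(g.part_seq("V-REGION"))
    within, between = [], []
    sgs = sorted(groups)
    for sg in sgs:
        seqs = groups[sg]
        for i in range(len(seqs)):
            for j in range(i + 1, len(seqs)):
                within.append(pairwise_identity(seqs[i], seqs[j]) / 100)
    for a in range(len(sgs)):
        for b in range(a + 1, len(sgs)):
            for sa in groups[sgs[a]]:
                for sb in groups[sgs[b]]:
                    between.append(pairwise_identity(sa, sb) / 100)
    assert np.mean(within) >= 0.80
    assert np.mean(between) <= 0.65


def test_infeasible_identity_constraints_fail_loudly():
    with pytest.raises(ValueError, match="infeasible"):
        simulate_germline_set(LocusSpec(within_subgroup_identity=0.70))
    with pytest.raises(ValueError):
        simulate_germline_set(LocusSpec(pseudogene_fraction=0.8, orf_fraction=0.5))


def test_locus_layout_strands_and_trdd_count(locus_sim):
    """Cluster genes inverted relative to the V array; 3 TRDD features."""
    vs = [g for g in locus_sim.genes if g.gene_type == "V"]
    cluster = [g for g in locus_sim.genes if g.gene_type != "V"]
    assert all(g.strand == "+" for g in vs)
    assert all(g.strand == "-" for g in cluster)
    assert max(g.end for g in vs) < min(g.start for g in cluster)
    assert sum(g.gene_type == "D" for g in locus_sim.genes) == 3
    d_lengths = sorted(
        g.parts["D-REGION"][1] - g.parts["D-REGION"][0]
        for g in locus_sim.genes
        if g.gene_type == "D"
    )
    assert d_lengths == [8, 13, 14]


def test_inverted_block_places_those_v_genes_on_the_cluster_strand():
    sim = simulate_locus(LocusSpec(n_subgroups=4, genes_per_subgroup=(2, 3),
                                   inverted_block=(1, 3), rng_seed=6))
    vs = sorted((g for g in sim.genes if g.gene_type == "V"),
                key=lambda g: -g.start)  # locus rank order
    assert [g.strand for g in vs[:3]] == ["-", "-", "-"]
    assert all(g.strand == "+" for g in vs[3:])


def test_locus_simulation_is_deterministic():
    a = simulate_locus(LocusSpec(n_subgroups=3, genes_per_subgroup=(2, 2), rng_seed=9))
    b = simulate_locus(LocusSpec(n_subgroups=3, genes_per_subgroup=(2, 2), rng_seed=9))
    assert a.genome == b.genome
    assert [g.name for g in a.genes] == [g.name for g in b.genes]


def test_repertoire_reads_deterministic_and_truth_consistent(locus_sim):
    spec = RepertoireSpec(n_reads=50, rng_seed=42)
    p1, t1 = simulate_repertoire_reads(locus_sim.germline_set(), spec)
    p2, t2 = simulate_repertoire_reads(locus_sim.germline_set(), spec)
    assert p1 == p2
    names_v = {g.name for g in locus_sim.genes if g.gene_type == "V"}
    names_j = {g.name for g in locus_sim.genes if g.gene_type == "J"}
    for t in t1:
        assert t["v_call"] in names_v and t["j_call"] in names_j


def test_uniform_usage_draws_are_multinomial(locus_sim):
    """Every V x J cell frequency within 3 binomial SD of its weight."""
    genes = locus_sim.germline_set()
    vs = [g for g in genes.genes if g.gene_type == "V" and g.functionality == "F"][:4]
    js = [g for g in genes.genes if g.gene_type == "J" and g.chain == "TRA"
          and g.functionality == "F"][:5]
    sub = vs + js + [g for g in genes.genes if g.gene_type == "C"]
    n = 1000
    spec = RepertoireSpec(n_reads=n, rng_seed=13)
    _pairs, truth = simulate_repertoire_reads(sub, spec)
    p = 1 / 20
    sd = (p * (1 - p) / n) ** 0.5
    for v in vs:
        for j in js:
            freq = sum(t["v_call"] == v.name and t["j_call"] == j.name
                       for t in truth) / n
            assert abs(freq - p) <= 3 * sd


def test_error_free_pairs_merge_back_to_amplicons(locus_sim, repertoire_sim):
    pairs, truth, _spec = repertoire_sim
    merged, dropped = merge_pairs([(r, a) for r, a, _ in pairs],
                                  [(r, b) for r, _, b in pairs])
    assert not dropped
    amps = {t["read_id"]: t["amplicon"] for t in truth}
    assert all(m.seq == amps[m.id] for m in merged)


def test_short_reads_rejected(locus_sim):
    with pytest.raises(ValueError, match="read_length"):
        simulate_repertoire_reads(locus_sim.germline_set(),
                                  RepertoireSpec(read_length=70))
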