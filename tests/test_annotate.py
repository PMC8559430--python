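"""Germline annotation: constant genes, V/J/D delimitation, functionality."""

from __future__ import annotations

import numpy as np
import pytest

from tralocus._seq import revcomp
from tralocus.annotate import (
    AnnotationConfig,
    annotate_locus,
    classify_functionality,
    find_constant_genes,
    write_annotation,
)
from tralocus.genemodel import RSHit, StructureConfig, pair_d_hits
from tralocus.records import read_gff3
from tralocus.simulate import LocusSpec, simulate_locus
from tralocus.subgroups import classify_locus
from conftest import core_set


def test_constant_genes_recovered_exactly(locus_sim):
    models = find_constant_genes(locus_sim.genome, locus_sim.c_queries(),
                                 contig=locus_sim.contig)
    truth = {g.chain: g for g in locus_sim.genes if g.gene_type == "C"}
    assert {m.chain for m in models} == {"TRA", "TRD"}
    for m in models:
        t = truth[m.chain]
        expected = sorted(t.genomic(t.parts[p]) for p in ("EX1", "EX2", "EX3"))
        assert sorted(m.exons) == expected
        assert m.strand == t.strand
        assert m.percent_identity == 100.0
        assert m.translated_len == 110  # three exons encoding a 110-aa chain
        assert m.splice_ok


def test_no_c_homolog_gives_empty_model_list():
    rng = np.random.default_rng(1)
    genome = "".join("ACGT"[i] for i in rng.integers(0, 4, 3000))
    assert find_constant_genes(genome, {"TRAC": "ATGGCCTGA" * 30}) == []


def test_constant_gene_on_reverse_strand(locus_sim):
    """Reverse-complementing the contig flips strands but keeps the models."""
    rc = revcomp(locus_sim.genome)
    models = find_constant_genes(rc, locus_sim.c_queries())
    assert {m.chain for m in models} == {"TRA", "TRD"}
    assert all(m.strand == "+" for m in models)  # cluster was on '-'
    n = len(locus_sim.genome)
    truth = {g.chain: g for g in locus_sim.genes if g.gene_type == "C"}
    for m in models:
        t = truth[m.chain]
        mirrored = sorted(
            (n - b, n - a) for a, b in (t.genomic(t.parts[p]) for p in ("EX1", "EX2", "EX3"))
        )
        assert sorted(m.exons) == mirrored


def test_mutation_free_locus_recovered_exactly(locus_sim, locus_annotation):
    """Round trip: every planted interval, strand and functionality exact."""
    assert core_set(locus_annotation.genes) == core_set(locus_sim.to_annotations())
    # part-level agreement for the rearranging genes
    truth_parts = {
        (g.gene_type, g.start, g.strand): {p: g.genomic(iv) for p, iv in g.parts.items()}
        for g in locus_sim.genes
    }
    for a in locus_annotation.genes:
        t = truth_parts[(a.gene_type, a.start, a.strand)]
        for part, iv in a.parts.items():
            if part in t:
                assert iv == t[part], (a.gene_type, part)


def test_planted_defects_map_to_expected_classes(locus_sim, locus_annotation):
    """stop/frameshift -> P; RS and splice defects -> ORF, recorded as such."""
    by_span = {(g.start, g.end): g for g in locus_annotation.genes}
    for t in locus_sim.genes:
        if t.gene_type != "V" or not t.defects:
            continue
        a = by_span[(t.start, t.end)]
        planted = t.defects[0]
        assert planted in a.defects
        assert a.functionality == t.functionality


def test_annotation_invariant_under_reverse_complement(locus_sim, locus_annotation):
    rc = revcomp(locus_sim.genome)
    ann_rc = annotate_locus(rc, locus_sim.c_queries(), contig=locus_sim.contig)
    classify_locus(ann_rc)
    assert ann_rc.orientation == "FWD"
    n = len(rc)

    def mirror(a):
        return (a.gene_type, a.contig, n - a.end, n - a.start,
                "+" if a.strand == "-" else "-", a.functionality)

    assert {mirror(a) for a in ann_rc.genes} == core_set(locus_annotation.genes)
    names = lambda ann: sorted(a.name for a in ann.genes if a.name)
    assert names(ann_rc) == names(locus_annotation)


def test_trdj_fgka_exempt_but_traj_motif_loss_demotes():
    assert classify_functionality(["missing_FGXG"], "J", "TRA") == "ORF"
    assert classify_functionality(["missing_FGXG"], "J", "TRD") == "F"
    assert classify_functionality([], "J", "TRA") == "F"
    assert classify_functionality(["stop_codon"], "J", "TRA") == "P"


def test_conserved_residue_policy_default_vs_strict():
    defects = ["missing_conserved_residue"]
    assert classify_functionality(defects, "V") == "F"
    assert classify_functionality(defects, "V", strict_conserved=True) == "ORF"
    assert classify_functionality(defects + ["rs_defect"], "V") == "ORF"
    assert classify_functionality(["frameshift"], "V") == "P"


def test_trdj_annotation_keeps_functionality_f(locus_annotation):
    (trdj,) = locus_annotation.of_type("J", "TRD")
    assert "missing_FGXG" in trdj.defects
    assert trdj.functionality == "F"
    assert "FGKA" in trdj.notes["j_aa"]


def test_d_regions_have_planted_lengths_and_open_frames(locus_annotation):
    ds = locus_annotation.of_type("D")
    assert sorted(d.notes["d_length"] for d in ds) == [8, 13, 14]
    for d in ds:
        assert all(d.notes["frames_open"])  # readable in all three frames


def test_distant_rs_pair_is_not_a_d_gene():
    h5 = RSHit("D5", "-", (1000, 1007), (1019, 1028), 12, 0, 0)
    h3 = RSHit("D3", "+", (6000, 6007), (6030, 6039), 23, 0, 0)
    assert pair_d_hits([h5], [h3], StructureConfig()) == []


def test_gff3_round_trip_and_census(tmp_path, locus_sim, locus_annotation):
    paths = write_annotation(locus_annotation, tmp_path)
    back = read_gff3(paths["gff3"])
    assert core_set(back) == core_set(locus_annotation.genes)
    by_name = {a.name: a for a in back if a.name}
    for a in locus_annotation.genes:
        if a.name:
            b = by_name[a.name]
            assert b.parts == a.parts and b.defects == a.defects
    # census equals the planted census (numbering follows the locus order)
    import pandas as pd

    census = pd.read_csv(paths["census"], sep="\t")
    planted: dict[int, dict] = {}
    for g in locus_sim.genes:
        if g.gene_type == "V" and g.functionality in ("F", "ORF"):
            row = planted.setdefault(g.subgroup, {"F": 0, "ORF": 0, "cdr": set()})
            row[g.functionality] += 1
            c1, c2, c3 = g.meta["cdr"]
            row["cdr"].add(f"[{c1}.{c2}.{c3}]")
    assert len(census) == len(planted)
    for _, row in census.iterrows():
        sg = int(row["subgroup"].removeprefix("TRAV"))
        assert row["n_F"] == planted[sg]["F"]
        assert row["n_ORF"] == planted[sg]["ORF"]
        assert set(row["cdr_lengths"].split()) == planted[sg]["cdr"]


def test_empty_annotation_writes_valid_gff3(tmp_path):
    from tralocus.records import write_gff3

    p = tmp_path / "empty.gff3"
    write_gff3([], p)
    assert p.read_text().startswith("##gff-version 3")
    assert read_gff3(p) == []
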