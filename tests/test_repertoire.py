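"""Repertoire pipeline: merging, assignment filters, productivity, usage."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from tralocus._seq import revcomp
from tralocus.repertoire import (
    GermlineDB,
    MergedRead,
    SegmentHit,
    assign_segments,
    assignments_to_airr,
    best_gapless_hits,
    classify_productivity,
    conditional_j_usage,
    filter_and_dedupe,
    merge_pairs,
    normalize_counts,
    run_pipeline_reads,
    size_factors,
    usage_tables,
)

BASES = "ACGT"


def rnd(n, seed):
    rng = np.random.default_rng(seed)
    return "".join(BASES[i] for i in rng.integers(0, 4, n))


# --------------------------------------------------------------- merging


def test_exact_overlap_merges_to_expected_length():
    amp = rnd(200, 1)
    r1, r2 = amp[:120], revcomp(amp[-110:])  # 30 nt overlap
    merged, dropped = merge_pairs([("r:1", r1)], [("r:1", r2)])
    assert not dropped
    assert len(merged[0].seq) == 120 + 110 - 30
    assert merged[0].seq == amp and merged[0].overlap_len == 30


def test_non_overlapping_pair_is_dropped_with_reason():
    merged, dropped = merge_pairs([("a:1", rnd(80, 2))], [("a:1", rnd(80, 3))])
    assert merged == [] and dropped == {"a:1": "no_overlap"}


def test_short_merge_product_is_dropped():
    amp = rnd(140, 4)
    merged, dropped = merge_pairs([("a:1", amp[:100])], [("a:1", revcomp(amp[-100:]))])
    assert dropped == {"a:1": "too_short"}  # merged length 140 <= 150


def test_mismatched_ids_raise():
    with pytest.raises(ValueError, match="id mismatch"):
        merge_pairs([("a", "ACGT" * 30)], [("b", "ACGT" * 30)])


def test_overlap_disagreement_resolved_towards_interior_base():
    amp = rnd(240, 5)
    r1 = amp[:150]
    r2_seq = amp[-150:]
    # error at the very 3' end of read 1 (position 149) inside the overlap
    r1_err = r1[:149] + ("A" if r1[149] != "A" else "C")
    merged, _ = merge_pairs([("x:1", r1_err)], [("x:1", revcomp(r2_seq))])
    assert merged[0].seq == amp  # read 2's copy is farther from its 3' end
    assert merged[0].mismatches == 1


# --------------------------------------------------- alignment and filters


def small_db():
    v = rnd(120, 10)
    j = rnd(51, 11)
    c = rnd(90, 12)
    return GermlineDB(refs={"V": [("TRAV1", v)], "J": [("TRAJ1", j)],
                            "C": [("TRAC", c)]})


def test_exact_segment_found_at_full_identity():
    db = small_db()
    v = db.refs["V"][0][1]
    read = rnd(40, 13) + v[:60] + rnd(40, 14)
    hits = [h for h in best_gapless_hits(read, db) if h.segment_class == "V"]
    assert len(hits) == 1
    h = hits[0]
    assert h.identity == 100.0 and h.length == 60
    assert h.read_start == 40 and h.q_start == 0 and h.strand == "+"


def test_one_mismatch_in_sixty_passes_floor_but_fails_assignment_filter():
    """98.3% identity is a valid hit (>=97) yet fails the >99.9% criterion."""
    db = small_db()
    v = db.refs["V"][0][1][:60]
    v_mut = v[:30] + ("A" if v[30] != "A" else "C") + v[31:]
    read = rnd(30, 15) + v_mut + rnd(30, 16)
    hits = [h for h in best_gapless_hits(read, db) if h.segment_class == "V"]
    assert hits and hits[0].length == 60
    assert abs(hits[0].identity - 100 * 59 / 60) < 1e-9
    mr = [MergedRead("r:1", "s", read, 30, 0)]
    _asg, dropped = filter_and_dedupe(hits_with_read_id(hits, "r:1"), mr)
    assert dropped["r:1"] in ("no_C", "V_identity")  # fails before/at V identity


def hits_with_read_id(hits, rid):
    for h in hits:
        h.read_id = rid
    return hits


def brute_force_gapless(query, read, min_identity=97.0, min_len=30):
    """Oracle: every diagonal, every subsegment, scored +1/-2."""
    best = None
    for d in range(-len(query) + 1, len(read)):
        q0, q1 = max(0, -d), min(len(query), len(read) - d)
        if q1 - q0 <= 0:
            continue
        mask = [query[q] == read[q + d] for q in range(q0, q1)]
        for b in range(len(mask)):
            s = 0
            for e in range(b, len(mask)):
                s += 1 if mask[e] else -2
                length = e - b + 1
                if length < min_len:
                    continue
                matches = sum(mask[b : e + 1])
                ident = 100 * matches / length
                if ident < min_identity:
                    continue
                key = (s, ident, -(q0 + b + d))
                if best is None or key > best[0]:
                    best = (key, s, length, ident)
    return best


def test_aligner_agrees_with_bruteforce_oracle_on_small_cases():
    rng = np.random.default_rng(20)
    ref = rnd(50, 21)
    db = GermlineDB(refs={"V": [("g", ref)], "J": [], "C": []})
    for seed in range(6):
        read = rnd(60, 100 + seed) + ref[5:45] + rnd(30, 200 + seed)
        # sprinkle a mismatch sometimes
        if seed % 2:
            read = read[:70] + ("A" if read[70] != "A" else "T") + read[71:]
        mine = [h for h in best_gapless_hits(read, db) if h.strand == "+"]
        oracle = brute_force_gapless(ref, read)
        if oracle is None:
            assert mine == []
        else:
            assert mine, f"oracle found a hit the aligner missed (seed {seed})"
            assert mine[0].score == oracle[1]
            assert mine[0].length == oracle[2]
            assert abs(mine[0].identity - oracle[3]) < 1e-9


def test_random_read_has_no_hits_against_unrelated_db():
    db = small_db()
    read = rnd(400, 99)
    assert best_gapless_hits(read, db) == []


def _fake_hit(rid, cls, gene, identity, length, log_e):
    return SegmentHit(read_id=rid, segment_class=cls, gene=gene, identity=identity,
                      length=length, score=length, log10_evalue=log_e,
                      read_start=0, read_end=length, q_start=0, q_end=length,
                      strand="+", ref_len=length)


def read_stub(rid):
    return MergedRead(rid, "s", "A" * 400, 30, 0)


@pytest.mark.parametrize(
    "c_len,j_id,v_id,v_len,expect",
    [
        (30, 100.0, 100.0, 60, "C_too_short"),  # 'greater than 30' is strict
        (31, 100.0, 100.0, 60, None),
        (60, 99.9, 100.0, 60, "J_identity"),  # 99.9 exactly fails
        (60, 100.0, 99.9, 60, "V_identity"),
        (60, 100.0, 100.0, 49, "V_too_short"),  # >= 50 is inclusive
        (60, 100.0, 100.0, 50, None),
    ],
)
def test_filter_boundaries_exactly_as_stated(c_len, j_id, v_id, v_len, expect):
    hits = [
        _fake_hit("r", "C", "TRAC", 100.0, c_len, -10),
        _fake_hit("r", "J", "TRAJ1", j_id, 45, -12),
        _fake_hit("r", "V", "TRAV1", v_id, v_len, -30),
    ]
    asg, dropped = filter_and_dedupe(hits, [read_stub("r")])
    if expect is None:
        assert len(asg) == 1 and not dropped
    else:
        assert dropped == {"r": expect}


def test_dedup_keeps_lowest_expectancy_then_identity_then_name():
    hits = [
        _fake_hit("r", "C", "TRAC", 100.0, 60, -10),
        _fake_hit("r", "J", "TRAJ1", 100.0, 45, -12),
        _fake_hit("r", "V", "TRAV9", 100.0, 60, -10),
        _fake_hit("r", "V", "TRAV2", 100.0, 120, -30),
        _fake_hit("r", "V", "TRAV1", 100.0, 120, -30),
    ]
    asg, _ = filter_and_dedupe(hits, [read_stub("r")])
    assert asg[0].v_call == "TRAV1"  # -30 beats -10; name breaks the tie


# --------------------------------------------------------- productivity


def _assignment_for(read, db):
    merged = [MergedRead("r:1", "s", read, 30, 0)]
    hits = assign_segments(merged, db)
    asg, dropped = filter_and_dedupe(hits, merged)
    assert asg, f"read failed filters: {dropped}"
    return asg[0]


def productivity_fixture(locus_sim):
    gl = locus_sim.germline_set()
    v = next(g for g in gl.genes if g.gene_type == "V" and g.functionality == "F")
    j = next(g for g in gl.genes if g.gene_type == "J" and g.chain == "TRA"
             and g.functionality == "F")
    c = next(g for g in gl.genes if g.gene_type == "C" and g.chain == "TRA")
    db = GermlineDB.from_germline_set(gl.genes)
    region = v.part_seq("V-REGION")
    jreg = j.part_seq("J-REGION")
    amp = v.leader_seq + region + jreg + c.part_seq("EX1")[:60]
    assert (len(v.leader_seq) + len(region) + len(jreg)) % 3 == 0
    return amp, len(v.leader_seq) + len(region), db


def test_in_frame_junction_is_productive(locus_sim):
    amp, _cut, db = productivity_fixture(locus_sim)
    a = _assignment_for(amp, db)
    assert classify_productivity(a, amp) == "productive"


def test_single_nt_insertion_in_junction_is_frameshift(locus_sim):
    amp, cut, db = productivity_fixture(locus_sim)
    shifted = amp[:cut] + "G" + amp[cut:]
    a = _assignment_for(shifted, db)
    assert classify_productivity(a, shifted) == "unproductive"


def test_in_frame_stop_in_junction_is_unproductive(locus_sim):
    amp, cut, db = productivity_fixture(locus_sim)
    stopped = amp[:cut] + "TAA" + amp[cut:]
    a = _assignment_for(stopped, db)
    assert classify_productivity(a, stopped) == "unproductive"


# ------------------------------------------------ end-to-end and usage


def test_error_free_repertoire_fully_recovered(locus_sim, repertoire_sim):
    """All pairs merge and every read gets its true V/J and productivity."""
    pairs, truth, spec = repertoire_sim
    merged, dropped = merge_pairs([(r, a) for r, a, _ in pairs],
                                  [(r, b) for r, _, b in pairs])
    assert len(merged) == len(pairs) and not dropped
    db = GermlineDB.from_germline_set(locus_sim.germline_set().genes)
    assignments, drop2 = run_pipeline_reads(merged, db)
    assert not drop2
    tr = {t["read_id"]: t for t in truth}
    for a in assignments:
        assert a.v_call == tr[a.read_id]["v_call"]
        assert a.j_call == tr[a.read_id]["j_call"]
        assert a.productive == tr[a.read_id]["productive"]
    got_frac = sum(a.productive for a in assignments) / len(assignments)
    assert got_frac == spec.productive_fraction


def test_usage_tables_partition_and_percentages(locus_sim, repertoire_sim):
    pairs, truth, _spec = repertoire_sim
    merged, _ = merge_pairs([(r, a) for r, a, _ in pairs],
                            [(r, b) for r, _, b in pairs])
    db = GermlineDB.from_germline_set(locus_sim.germline_set().genes)
    assignments, _ = run_pipeline_reads(merged, db)
    usage = usage_tables(assignments)
    um_p = usage["fish1"]["productive"]
    um_u = usage["fish1"]["unproductive"]
    total = um_p.vj_counts.values.sum() + um_u.vj_counts.values.sum()
    assert total == len(assignments)  # productive/unproductive partition
    assert abs(um_p.frequencies.values.sum() - 100.0) < 1e-9
    assert (um_p.v_marginal.sum() == um_p.vj_counts.values.sum())
    cond = conditional_j_usage(um_p)
    sums = cond.sum(axis=1)
    used = um_p.vj_counts.sum(axis=1) > 0
    assert np.allclose(sums[used], 100.0)
    airr = assignments_to_airr(assignments)
    assert set(airr.columns) >= {"sequence_id", "v_call", "j_call", "productive"}
    assert len(airr) == len(assignments)


def test_forty_of_hundred_reads_give_forty_percent():
    from tralocus.repertoire import ReadAssignment

    asg = []
    for i in range(100):
        v = "TRAV2-1" if i < 40 else "TRAV3-1"
        asg.append(ReadAssignment(f"r{i}", "s", v, "TRAJ1", "TRAC", True, "",
                                  None, None, None))
    um = usage_tables(asg)["s"]["productive"]
    assert um.frequencies.loc["TRAV2-1", "TRAJ1"] == 40.0


# ------------------------------------------------------- normalisation


def test_normalization_single_sample_direct_arithmetic():
    """Size factor is the sample's geometric mean of nonzero counts."""
    counts = pd.DataFrame({"s1": [0, 1, 3]})
    sf = size_factors(counts)
    assert abs(sf["s1"] - np.sqrt(3)) < 1e-12
    norm = normalize_counts(counts)
    expect = np.log2(np.array([0, 1, 3]) / np.sqrt(3) + 1)
    assert np.allclose(norm["s1"], expect)


def test_doubled_sample_has_identical_normalized_values():
    c1 = pd.DataFrame({"s1": [0, 1, 3, 10], "s2": [0, 2, 6, 20]})
    n = normalize_counts(c1)
    assert np.allclose(n["s1"], n["s2"])


def test_doubling_one_sample_leaves_every_normalized_column_unchanged():
    c = pd.DataFrame({"s1": [1, 5, 3, 10], "s2": [4, 2, 6, 20], "s3": [2, 2, 9, 5]})
    doubled = c.copy()
    doubled["s2"] = doubled["s2"] * 2
    n0, n1 = normalize_counts(c), normalize_counts(doubled)
    for col in c.columns:
        assert np.allclose(n0[col], n1[col])


def test_normalization_is_monotone_within_sample():
    c = pd.DataFrame({"s1": [0, 1, 2, 7, 7, 50], "s2": [3, 1, 4, 1, 5, 9]})
    n = normalize_counts(c)
    for col in c.columns:
        order = np.argsort(c[col].values, kind="stable")
        assert (np.diff(n[col].values[order]) >= -1e-12).all()


def test_all_zero_sample_is_an_error():
    with pytest.raises(ValueError, match="nonzero"):
        size_factors(pd.DataFrame({"s1": [0, 0, 0]}))
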