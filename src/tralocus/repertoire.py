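"""5'-RACE TR-alpha repertoire processing.

The pipeline mirrors a C-primed amplicon workflow: read pairs are merged by
maximal overlap (FLASH-style), merged reads are aligned against a local
germline database of C, J and V reference segments, and reads survive only
with a C hit longer than 30 bp, a J hit above 99.9% identity, and a V hit
above 99.9% identity over at least 50 bp (hits below a 97% identity floor
are never reported).  Surviving reads are called productive or unproductive
by translating through the V-J junction into the constant region, and
usage is summarised as V x J matrices, marginals and normalised tables.

Segment alignment is substitution-only (gapless) seed-and-extend: for every
shared 15-mer diagonal the optimal local segment (match +1 / mismatch -2) is
taken.  At the reported thresholds (>=97% identity over >=30 bp) every hit
necessarily contains an exact 15-mer, so this agrees exactly with exhaustive
enumeration of gapless local alignments.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._seq import revcomp, translate

SEED_K = 15
#: Karlin-Altschul-style parameters for the +1/-2 scoring; only the
#: monotonicity of the expectancy in (score, search space) matters downstream.
KA_LAMBDA = 1.28
KA_LNK = math.log(0.46)


# ---------------------------------------------------------------------------
# Read-pair merging
# ---------------------------------------------------------------------------


@dataclass
class MergedRead:
    """A merged (extended) read."""

    id: str
    sample: str
    seq: str
    overlap_len: int
    mismatches: int


def _read_pairs(r1, r2):
    if isinstance(r1, (str, Path)):
        from Bio import SeqIO

        rec1 = list(SeqIO.parse(str(r1), "fastq"))
        rec2 = list(SeqIO.parse(str(r2), "fastq"))
        r1 = [(rec.id.removesuffix("/1"), str(rec.seq)) for rec in rec1]
        r2 = [(rec.id.removesuffix("/2"), str(rec.seq)) for rec in rec2]
    return r1, r2


def merge_pairs(
    r1,
    r2,
    min_len: int = 150,
    min_overlap: int = 10,
    max_mismatch_density: float = 0.25,
    sample: str | None = None,
):
    """Merge read pairs by maximal overlap.

    ``r1``/``r2`` are FASTQ paths or lists of ``(id, seq)``.  The overlap
    with the lowest mismatch density (largest overlap on ties) is chosen;
    disagreeing bases are resolved towards the mate in which the position
    lies farther from the sequencing 3' end.  Merged reads must exceed
    ``min_len``.  Returns ``(merged, dropped)`` where ``dropped`` maps read
    id to the first failing criterion.
    """
    r1, r2 = _read_pairs(r1, r2)
    if len(r1) != len(r2):
        raise ValueError("R1 and R2 have different read counts")
    merged: list[MergedRead] = []
    dropped: dict[str, str] = {}
    for (id1, s1), (id2, s2raw) in zip(r1, r2):
        if id1 != id2:
            raise ValueError(f"read id mismatch: {id1!r} vs {id2!r}")
        s2 = revcomp(s2raw)
        o, mm = _best_overlap(s1, s2, min_overlap, max_mismatch_density)
        if o is None:
            dropped[id1] = "no_overlap"
            continue
        seq = _merge_at(s1, s2, o)
        if len(seq) <= min_len:
            dropped[id1] = "too_short"
            continue
        smp = sample or (id1.split(":", 1)[0] if ":" in id1 else "sample1")
        merged.append(MergedRead(id=id1, sample=smp, seq=seq, overlap_len=o, mismatches=mm))
    return merged, dropped


def _best_overlap(s1: str, s2: str, min_overlap: int, max_density: float):
    max_o = min(len(s1), len(s2))
    # fast path: largest exact overlap
    probe = s2[: min(SEED_K, min_overlap)]
    start = max(0, len(s1) - max_o)
    while True:
        p = s1.find(probe, start)
        if p < 0:
            break
        o = len(s1) - p
        if o >= min_overlap and s1[p:] == s2[:o]:
            return o, 0
        start = p + 1
    a1 = np.frombuffer(s1.encode(), dtype=np.uint8)
    a2 = np.frombuffer(s2.encode(), dtype=np.uint8)
    best = None
    for o in range(max_o, min_overlap - 1, -1):
        mm = int(np.count_nonzero(a1[len(s1) - o :] != a2[:o]))
        d = mm / o
        if d <= max_density and (best is None or d < best[0]):
            best = (d, o, mm)
    if best is None:
        return None, None
    return best[1], best[2]


def _merge_at(s1: str, s2: str, o: int) -> str:
    p = len(s1) - o
    overlap = []
    for k in range(o):
        b1, b2 = s1[p + k], s2[k]
        if b1 == b2:
            overlap.append(b1)
        else:
            # distance from the 3' end of each original read
            overlap.append(b1 if (o - 1 - k) >= k else b2)
    return s1[:p] + "".join(overlap) + s2[o:]


# ---------------------------------------------------------------------------
# Germline database and segment assignment
# ---------------------------------------------------------------------------


@dataclass
class GermlineDB:
    """Reference segments per class (C, J, V) with a shared 15-mer index."""

    refs: dict[str, list[tuple[str, str]]]
    _index: dict = field(default=None, repr=False)
    _arrays: dict = field(default=None, repr=False)

    def __post_init__(self):
        if not any(self.refs.get(c) for c in ("C", "J", "V")):
            raise ValueError("germline database is empty")
        self._index = defaultdict(list)
        self._arrays = {}
        for cls, entries in self.refs.items():
            for ri, (name, seq) in enumerate(entries):
                seq = seq.upper()
                self._arrays[(cls, ri)] = np.frombuffer(seq.encode(), dtype=np.uint8)
                for q in range(len(seq) - SEED_K + 1):
                    self._index[seq[q : q + SEED_K]].append((cls, ri, q))

    def class_length(self, cls: str) -> int:
        return sum(len(s) for _, s in self.refs.get(cls, []))

    @classmethod
    def from_germline_set(cls, genes) -> "GermlineDB":
        """Build from simulated/annotated germline gene records.

        Uses F/ORF V-REGIONs, functional TRAJ J-REGIONs and the TRAC EX1.
        """
        refs: dict[str, list[tuple[str, str]]] = {"C": [], "J": [], "V": []}
        for g in genes:
            if g.gene_type == "V" and g.functionality in ("F", "ORF"):
                refs["V"].append((g.name or f"V{len(refs['V']) + 1}", g.part_seq("V-REGION")))
            elif g.gene_type == "J" and g.chain == "TRA" and g.functionality == "F":
                refs["J"].append((g.name or f"J{len(refs['J']) + 1}", g.part_seq("J-REGION")))
            elif g.gene_type == "C" and g.chain == "TRA":
                refs["C"].append((g.name or "TRAC", g.part_seq("EX1")))
        return cls(refs=refs)

    @classmethod
    def from_fasta(cls, path) -> "GermlineDB":
        """Read references from FASTA; class comes from a ``class=`` tag in the
        description or is inferred from TRAV/TRAJ/TRAC-style names."""
        from Bio import SeqIO

        refs: dict[str, list[tuple[str, str]]] = {"C": [], "J": [], "V": []}
        for rec in SeqIO.parse(str(path), "fasta"):
            tag = None
            for tok in rec.description.split():
                if tok.startswith("class="):
                    tag = tok.split("=", 1)[1]
            if tag is None:
                name = rec.id.upper()
                for key, t in (("AV", "V"), ("DV", "V"), ("AJ", "J"), ("DJ", "J"),
                               ("AC", "C"), ("DC", "C")):
                    if name[2:4] == key:
                        tag = t
            if tag not in ("C", "J", "V"):
                raise ValueError(f"cannot infer segment class for {rec.id}")
            refs[tag].append((rec.id, str(rec.seq)))
        return cls(refs=refs)


@dataclass
class SegmentHit:
    """Best gapless local alignment of one reference segment on a read."""

    read_id: str
    segment_class: str
    gene: str
    identity: float
    length: int
    score: int
    log10_evalue: float
    read_start: int
    read_end: int
    q_start: int
    q_end: int
    strand: str
    ref_len: int

    @property
    def expectancy(self) -> float:
        return 10.0 ** max(self.log10_evalue, -320.0)


def _kadane(mask: np.ndarray):
    """Best-scoring segment (match +1 / mismatch -2) of a boolean match mask.

    Ties resolve to the segment with the smallest end, then the largest
    start — i.e. the shortest (highest-identity) maximal-scoring segment.
    """
    s = np.where(mask, 1, -2).astype(np.int64)
    prefix = np.concatenate(([0], np.cumsum(s)))
    runmin = np.minimum.accumulate(prefix[:-1])
    gains = prefix[1:] - runmin
    e = int(np.argmax(gains))
    score = int(gains[e])
    b = int(np.nonzero(prefix[: e + 1] == runmin[e])[0][-1])
    return score, b, e + 1


def best_gapless_hits(
    read_seq: str, db: GermlineDB, min_identity: float = 97.0, min_len: int = 30
) -> list[SegmentHit]:
    """Best qualifying hit per reference segment on one read (both strands)."""
    hits: dict[tuple[str, int], SegmentHit] = {}
    for strand, seq in (("+", read_seq), ("-", revcomp(read_seq))):
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        diags: dict[tuple[str, int], set[int]] = defaultdict(set)
        for p in range(len(seq) - SEED_K + 1):
            for cls, ri, q in db._index.get(seq[p : p + SEED_K], ()):
                diags[(cls, ri)].add(p - q)
        for (cls, ri), ds in diags.items():
            ref = db._arrays[(cls, ri)]
            name, refseq = db.refs[cls][ri]
            for d in sorted(ds):
                q0 = max(0, -d)
                q1 = min(len(ref), len(arr) - d)
                if q1 - q0 < min_len:
                    continue
                mask = arr[q0 + d : q1 + d] == ref[q0:q1]
                score, b, e = _kadane(mask)
                length = e - b
                if length < min_len:
                    continue
                matches = (score + 2 * length) // 3
                identity = 100.0 * matches / length
                if identity < min_identity:
                    continue
                log10_e = (
                    math.log10(len(read_seq)) + math.log10(max(db.class_length(cls), 1))
                    + (KA_LNK - KA_LAMBDA * score) / math.log(10)
                )
                hit = SegmentHit(
                    read_id="",
                    segment_class=cls,
                    gene=name,
                    identity=identity,
                    length=length,
                    score=score,
                    log10_evalue=log10_e,
                    read_start=q0 + b + d,
                    read_end=q0 + e + d,
                    q_start=q0 + b,
                    q_end=q0 + e,
                    strand=strand,
                    ref_len=len(refseq),
                )
                key = (cls, ri)
                prev = hits.get(key)
                if prev is None or (hit.score, hit.identity, -hit.read_start) > (
                    prev.score, prev.identity, -prev.read_start
                ):
                    hits[key] = hit
    return list(hits.values())


def assign_segments(
    reads: list[MergedRead], db: GermlineDB,
    min_identity: float = 97.0, min_len: int = 30,
) -> list[SegmentHit]:
    """Align every read against the germline database.

    Only hits at >= ``min_identity`` percent identity over >= ``min_len``
    aligned bases are reported (the 97%/30 bp floor); the stricter
    per-class assignment criteria are applied later.
    """
    out = []
    for r in reads:
        for h in best_gapless_hits(r.seq, db, min_identity, min_len):
            h.read_id = r.id
            out.append(h)
    return out


# ---------------------------------------------------------------------------
# Filtering, dedup and productivity
# ---------------------------------------------------------------------------


@dataclass
class ReadAssignment:
    """A read that passed all per-class criteria."""

    read_id: str
    sample: str
    v_call: str
    j_call: str
    c_call: str
    productive: bool | None
    junction: str
    v_hit: SegmentHit
    j_hit: SegmentHit
    c_hit: SegmentHit


def _best_per_class(hits: list[SegmentHit]) -> dict[str, SegmentHit]:
    """Sort hits by expectancy and keep the single best per class
    (duplicate removal); ties break towards higher identity then name."""
    best: dict[str, SegmentHit] = {}
    for h in sorted(hits, key=lambda h: (h.log10_evalue, -h.identity, h.gene)):
        best.setdefault(h.segment_class, h)
    return best


def filter_and_dedupe(
    hits: list[SegmentHit],
    reads: list[MergedRead],
    c_min_len: int = 30,
    j_min_identity: float = 99.9,
    v_min_identity: float = 99.9,
    v_min_len: int = 50,
):
    """Apply the per-class assignment criteria.

    A read is assigned only with a C hit longer than ``c_min_len`` bases, a
    J hit with identity strictly above ``j_min_identity`` and a V hit with
    identity strictly above ``v_min_identity`` over at least ``v_min_len``
    bases.  Returns ``(assignments, dropped)``; each dropped read carries
    its first failing criterion.
    """
    by_read: dict[str, list[SegmentHit]] = defaultdict(list)
    for h in hits:
        by_read[h.read_id].append(h)
    read_by_id = {r.id: r for r in reads}
    assignments: list[ReadAssignment] = []
    dropped: dict[str, str] = {}
    for r in reads:
        best = _best_per_class(by_read.get(r.id, []))
        c, j, v = best.get("C"), best.get("J"), best.get("V")
        if c is None:
            dropped[r.id] = "no_C"
            continue
        if c.length <= c_min_len:
            dropped[r.id] = "C_too_short"
            continue
        if j is None:
            dropped[r.id] = "no_J"
            continue
        if j.identity <= j_min_identity:
            dropped[r.id] = "J_identity"
            continue
        if v is None:
            dropped[r.id] = "no_V"
            continue
        if v.identity <= v_min_identity:
            dropped[r.id] = "V_identity"
            continue
        if v.length < v_min_len:
            dropped[r.id] = "V_too_short"
            continue
        junction = ""
        if v.strand == j.strand:
            seq = r.seq if v.strand == "+" else revcomp(r.seq)
            if v.read_end <= j.read_start:
                junction = seq[v.read_end : j.read_start]
        assignments.append(
            ReadAssignment(
                read_id=r.id,
                sample=r.sample,
                v_call=v.gene,
                j_call=j.gene,
                c_call=c.gene,
                productive=None,
                junction=junction,
                v_hit=v,
                j_hit=j,
                c_hit=c,
            )
        )
    return assignments, dropped


def classify_productivity(assignment: ReadAssignment, merged_seq: str) -> str:
    """Call a V-J rearrangement productive or unproductive.

    Productive means: V and J lie on the same read strand, their germline
    reading frames are concordant (the distance from the V-REGION frame
    anchor to the J-REGION 3' end is a multiple of three), and the
    translation from the V anchor through the junction and J into the
    start of the constant region is stop-free.
    """
    v, j = assignment.v_hit, assignment.j_hit
    if v.strand != j.strand:
        return "unproductive"
    seq = merged_seq if v.strand == "+" else revcomp(merged_seq)
    anchor = v.read_start - v.q_start  # read position of V-REGION base 0
    j_end = j.read_end + (j.ref_len - j.q_end)
    if anchor < 0 or j_end > len(seq) or j_end <= anchor:
        return "unproductive"
    if (j_end - anchor) % 3 != 0:
        return "unproductive"
    stop = min(len(seq), j_end + 15)
    segment = seq[anchor : anchor + ((stop - anchor) // 3) * 3]
    return "unproductive" if "*" in translate(segment) else "productive"


def run_pipeline_reads(
    merged: list[MergedRead], db: GermlineDB, **filter_kwargs
) -> tuple[list[ReadAssignment], dict[str, str]]:
    """assign -> filter/dedup -> productivity for a batch of merged reads."""
    hits = assign_segments(merged, db)
    assignments, dropped = filter_and_dedupe(hits, merged, **filter_kwargs)
    seq_by_id = {r.id: r.seq for r in merged}
    for a in assignments:
        a.productive = classify_productivity(a, seq_by_id[a.read_id]) == "productive"
    return assignments, dropped


def assignments_to_airr(assignments: list[ReadAssignment]) -> pd.DataFrame:
    """AIRR-style rearrangement table (one row per assigned read)."""
    return pd.DataFrame(
        [
            {
                "sequence_id": a.read_id,
                "sample": a.sample,
                "v_call": a.v_call,
                "j_call": a.j_call,
                "c_call": a.c_call,
                "productive": bool(a.productive),
                "junction": a.junction,
            }
            for a in assignments
        ],
        columns=["sequence_id", "sample", "v_call", "j_call", "c_call",
                 "productive", "junction"],
    )


# ---------------------------------------------------------------------------
# Counting and normalisation
# ---------------------------------------------------------------------------


@dataclass
class UsageMatrix:
    """Per-sample V x J usage: raw counts, marginals and frequencies."""

    sample: str
    productive: bool
    vj_counts: pd.DataFrame  # V rows x J columns
    v_marginal: pd.Series
    j_marginal: pd.Series
    frequencies: pd.DataFrame  # percent of the sample's reads in this set


def usage_tables(
    assignments: list[ReadAssignment],
    v_genes: list[str] | None = None,
    j_genes: list[str] | None = None,
) -> dict[str, dict[str, UsageMatrix]]:
    """Per-sample V x J count matrices for productive and unproductive reads.

    ``v_genes``/``j_genes`` fix row/column order (defaults to sorted names
    seen in the data).  Frequencies are percentages of the sample's read
    total within each productivity class and sum to 100.
    """
    if v_genes is None:
        v_genes = sorted({a.v_call for a in assignments})
    if j_genes is None:
        j_genes = sorted({a.j_call for a in assignments})
    out: dict[str, dict[str, UsageMatrix]] = {}
    samples = sorted({a.sample for a in assignments})
    for sample in samples:
        out[sample] = {}
        for label, flag in (("productive", True), ("unproductive", False)):
            counts = pd.DataFrame(0, index=v_genes, columns=j_genes, dtype=int)
            for a in assignments:
                if a.sample == sample and a.productive == flag:
                    if a.v_call in counts.index and a.j_call in counts.columns:
                        counts.loc[a.v_call, a.j_call] += 1
            total = counts.values.sum()
            freq = counts * (100.0 / total) if total else counts.astype(float)
            out[sample][label] = UsageMatrix(
                sample=sample,
                productive=flag,
                vj_counts=counts,
                v_marginal=counts.sum(axis=1),
                j_marginal=counts.sum(axis=0),
                frequencies=freq,
            )
    return out


def conditional_j_usage(usage: UsageMatrix) -> pd.DataFrame:
    """Per-V conditional J-usage profile: rows sum to 100% (V genes with no
    reads give all-zero rows)."""
    counts = usage.vj_counts
    totals = counts.sum(axis=1)
    cond = counts.div(totals.where(totals > 0, 1), axis=0) * 100.0
    cond[totals == 0] = 0.0
    return cond


def j_usage_by_position(
    usage: UsageMatrix, positions: dict[str, int]
) -> pd.DataFrame:
    """J-gene usage versus genomic position (scatterplot table)."""
    freq = usage.frequencies.sum(axis=0)
    rows = [
        {"j_call": j, "position": positions.get(j), "frequency_pct": freq[j]}
        for j in usage.vj_counts.columns
    ]
    return pd.DataFrame(rows, columns=["j_call", "position", "frequency_pct"])


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Scale-decoupled median-of-ratios size factors.

    Each sample's library scale (the geometric mean of its nonzero counts)
    is factored out before building the geometric-mean pseudo-reference
    across samples, then multiplied back into the median-of-ratios factor.
    This keeps the classical median-of-ratios behaviour while making each
    sample's normalised values exactly invariant to rescaling that sample's
    library (doubling all of a sample's counts doubles its size factor).
    """
    if counts.shape[1] < 1:
        raise ValueError("need at least one sample")
    g = {}
    for col in counts.columns:
        pos = counts[col][counts[col] > 0]
        if pos.empty:
            raise ValueError(f"sample {col!r} has no nonzero counts")
        g[col] = float(np.exp(np.log(pos).mean()))
    scaled = counts / pd.Series(g)
    valid = (counts > 0).all(axis=1)  # zeros excluded from the pseudo-reference
    if not valid.any():
        raise ValueError("no feature is nonzero in every sample")
    ref = np.exp(np.log(scaled[valid]).mean(axis=1))
    sf = {}
    for col in counts.columns:
        ratios = scaled.loc[valid, col] / ref
        sf[col] = g[col] * float(np.median(ratios))
    return pd.Series(sf)


def normalize_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """log2-scale normalised counts: ``log2(count / size_factor + 1)``.

    A documented stand-in for a regularised log transform: size factors are
    median-of-ratios against a geometric-mean pseudo-reference (zeros
    excluded), computed on library-scale-decoupled profiles so that the
    result is monotone within a sample and invariant to per-sample
    library rescaling.
    """
    sf = size_factors(counts)
    return np.log2(counts / sf + 1.0)
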