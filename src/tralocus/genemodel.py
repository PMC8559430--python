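"""Structural model of TRA/TRD germline genes.

This module is the shared "grammar" of the locus: the recombination-signal
(RS) consensus and scanning thresholds, and the structural delimitation of
V, J and D genes around an RS match.  Both the synthetic-locus generator and
the annotator speak this grammar — the generator uses it to guarantee that
every planted gene is the unique best-scoring structure in its neighbourhood,
the annotator to delimit genes in unknown sequence.

Coordinate conventions: 0-based half-open throughout; hits carry genomic
coordinates on the forward strand regardless of the strand the motif reads on.

The canonical RS is heptamer CACAGTG / nonamer ACAAAAACC separated by a
spacer of roughly 12 or 23 bp.  In genomic sequence the heptamer always abuts
the coding region and reads 5'->3' *away* from it, which gives the following
equivalences used below (all on the strand where the motif reads canonically,
heptamer first):

* 23-spacer family (V-RS, 3'D-RS): the coding region lies immediately
  5' of the heptamer *on the same strand* as the motif.
* 12-spacer family (J-RS, 5'D-RS): the coding region lies immediately
  beyond the heptamer on the *opposite* strand (its reverse complement abuts
  the heptamer on the motif strand).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from ._seq import has_stop, revcomp, translate

HEPTAMER = "CACAGTG"
NONAMER = "ACAAAAACC"

#: J hallmark motif: Phe-Gly-X-Gly in the J-REGION reading frame.
FGXG_RE = re.compile(r"FG.G")

SPACER_WINDOWS = {
    "V": (22, 23),
    "J": (11, 13),
    "D5": (11, 13),
    "D3": (22, 23),
}

PREFERRED_SPACER = {"V": 22, "J": 12, "D5": 12, "D3": 23}

#: which structural family a kind belongs to (coding side, see module docs)
SAME_STRAND_CODING = {"V": True, "D3": True, "J": False, "D5": False}


@dataclass(frozen=True)
class RSConfig:
    """Detection and functionality thresholds for RS motif scanning.

    The detection thresholds admit degenerate signals so that genes with an
    RS defect remain discoverable; the (stricter) ``functional_*`` maxima
    define what counts as an RS "compatible with effective rearrangement"
    when classifying functionality.
    """

    max_heptamer_mm: int = 1
    heptamer_exact_prefix: int = 3  # the CAC core must match exactly
    max_nonamer_mm: int = 3
    functional_heptamer_mm: int = 0
    functional_nonamer_mm: int = 1


@dataclass(frozen=True)
class StructureConfig:
    """Expected gene architecture used to delimit coding regions.

    Lengths are in nucleotides.  The leader model (L-PART1 of fixed length
    ending at a GT donor, an intron, an AG acceptor, then an 11-nt L-PART2)
    follows the common TR V-gene exon layout; the preferred V intron and
    V-REGION lengths only break ties between otherwise equally supported
    structures.
    """

    l_part1_len: int = 37
    l_part2_len: int = 11
    min_v_intron: int = 80
    max_v_intron: int = 120
    pref_v_intron: int = 100
    min_v_region: int = 200
    max_v_region: int = 360
    pref_v_region: int = 294
    min_j_region: int = 30
    max_j_region: int = 80
    pref_j_region: int = 51
    min_d_region: int = 4
    max_d_region: int = 40
    min_c_intron: int = 70
    max_c_intron: int = 130

    @property
    def max_v_span(self) -> int:
        """Largest distance from heptamer start back to the leader ATG."""
        return (
            self.max_v_region + self.l_part2_len + 2 + self.max_v_intron + self.l_part1_len
        )


@dataclass(frozen=True)
class RSHit:
    """A heptamer/spacer/nonamer match.

    ``strand`` is the strand on which the motif reads canonically
    (heptamer 5' of nonamer).  ``heptamer``/``nonamer`` are forward-strand
    genomic intervals.  ``flank`` is the genomic coordinate of the boundary
    between the heptamer and the adjacent coding region.
    """

    kind: str
    strand: str
    heptamer: tuple[int, int]
    nonamer: tuple[int, int]
    spacer_len: int
    heptamer_mm: int
    nonamer_mm: int

    @property
    def total_mm(self) -> int:
        return self.heptamer_mm + self.nonamer_mm

    @property
    def flank(self) -> int:
        return self.heptamer[0] if self.strand == "+" else self.heptamer[1]

    @property
    def coding_strand(self) -> str:
        if SAME_STRAND_CODING[self.kind]:
            return self.strand
        return "-" if self.strand == "+" else "+"

    def span(self) -> tuple[int, int]:
        lo = min(self.heptamer[0], self.nonamer[0])
        hi = max(self.heptamer[1], self.nonamer[1])
        return lo, hi

    def sort_key(self):
        dev = abs(self.spacer_len - PREFERRED_SPACER[self.kind])
        return (self.total_mm, dev, self.heptamer[0], self.strand)


def _mismatch_profile(arr: np.ndarray, pattern: str) -> np.ndarray:
    """Per-offset mismatch counts of ``pattern`` against a uint8 sequence."""
    k = len(pattern)
    if arr.size < k:
        return np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(arr, k)
    pat = np.frombuffer(pattern.encode(), dtype=np.uint8)
    return (win != pat).sum(axis=1)


def _scan_strand(seq: str, kind: str, cfg: RSConfig) -> list[tuple[int, int, int, int]]:
    """Canonical-motif matches on one strand: (hept_start, spacer, hmm, nmm)."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    hmm = _mismatch_profile(arr, HEPTAMER)
    pre = _mismatch_profile(arr, HEPTAMER[: cfg.heptamer_exact_prefix])
    nmm = _mismatch_profile(arr, NONAMER)
    lo, hi = SPACER_WINDOWS[kind]
    out = []
    cand = np.nonzero((hmm <= cfg.max_heptamer_mm) & (pre[: hmm.size] == 0))[0]
    for p in cand.tolist():
        for s in range(lo, hi + 1):
            q = p + 7 + s
            if q < nmm.size and nmm[q] <= cfg.max_nonamer_mm:
                out.append((p, s, int(hmm[p]), int(nmm[q])))
    return out


def scan_rs(
    genome: str,
    kind: str,
    window: tuple[int, int] | None = None,
    config: RSConfig | None = None,
) -> list[RSHit]:
    """Scan both strands for RS motifs of the given kind.

    ``window`` restricts the scan to a forward-strand genomic interval.
    Hits are returned sorted by composite score: fewest total mismatches,
    then smallest deviation of the spacer from its preferred length.
    """
    if kind not in SPACER_WINDOWS:
        raise ValueError(f"unknown RS kind {kind!r}")
    cfg = config or RSConfig()
    off = 0
    sub = genome
    if window is not None:
        off = window[0]
        sub = genome[window[0] : window[1]]
    n = len(sub)
    hits: list[RSHit] = []
    for p, s, hm, nm in _scan_strand(sub, kind, cfg):
        hits.append(
            RSHit(kind, "+", (off + p, off + p + 7), (off + p + 7 + s, off + p + 16 + s), s, hm, nm)
        )
    for p, s, hm, nm in _scan_strand(revcomp(sub), kind, cfg):
        # position p on the reverse strand maps to genomic [n-p-7, n-p)
        h = (off + n - p - 7, off + n - p)
        nona = (off + n - p - 16 - s, off + n - p - 7 - s)
        hits.append(RSHit(kind, "-", h, nona, s, hm, nm))
    hits.sort(key=RSHit.sort_key)
    return hits


# ---------------------------------------------------------------------------
# V-gene structural candidates
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VCandidate:
    """A candidate V-gene structure on a sense-oriented window.

    All positions are relative to the sense window; the V-REGION ends at
    ``region_end`` (the heptamer start).  ``signals`` counts how many of the
    three delimiting signals (AG acceptor, GT donor, ATG start) are canonical.
    """

    region_start: int
    region_end: int
    intron_len: int
    atg_start: int
    acceptor_ok: bool
    donor_ok: bool
    atg_ok: bool
    leader_stop_free: bool

    @property
    def region_len(self) -> int:
        return self.region_end - self.region_start

    @property
    def signals(self) -> int:
        return int(self.acceptor_ok) + int(self.donor_ok) + int(self.atg_ok)

    def parts(self, cfg: StructureConfig) -> dict[str, tuple[int, int]]:
        lp2_start = self.region_start - cfg.l_part2_len
        return {
            "L-PART1": (self.atg_start, self.atg_start + cfg.l_part1_len),
            "V-INTRON": (self.atg_start + cfg.l_part1_len, lp2_start),
            "L-PART2": (lp2_start, self.region_start),
            "V-REGION": (self.region_start, self.region_end),
        }

    def score(self, cfg: StructureConfig):
        return (
            self.signals,
            self.leader_stop_free,
            -abs(self.intron_len - cfg.pref_v_intron),
            -abs(self.region_len - cfg.pref_v_region),
            -self.region_len,
            -self.intron_len,
        )


def v_structure_candidates(
    sense: str, region_end: int, cfg: StructureConfig | None = None
) -> list[VCandidate]:
    """Enumerate V-gene structures whose V-REGION ends at ``region_end``.

    A structure is (leader ATG + L-PART1 | GT..intron..AG | L-PART2 |
    V-REGION); at least two of the three delimiting signals must be
    canonical so that genes with a single planted splice defect remain
    discoverable.  Candidates are returned best-first under the
    deterministic score of :meth:`VCandidate.score`.
    """
    cfg = cfg or StructureConfig()
    lp2 = cfg.l_part2_len
    out: list[VCandidate] = []
    max_region = min(cfg.max_v_region, region_end - lp2 - 2)
    for L in range(cfg.min_v_region, max_region + 1):
        r0 = region_end - L
        acc_ok = sense[r0 - lp2 - 2 : r0 - lp2] == "AG"
        for i in range(cfg.min_v_intron, cfg.max_v_intron + 1):
            d0 = r0 - lp2 - i
            a0 = d0 - cfg.l_part1_len
            if a0 < 0:
                continue
            don_ok = sense[d0 : d0 + 2] == "GT"
            atg_ok = sense[a0 : a0 + 3] == "ATG"
            if int(acc_ok) + int(don_ok) + int(atg_ok) < 2:
                continue
            leader = sense[a0:d0] + sense[r0 - lp2 : r0]
            out.append(
                VCandidate(
                    region_start=r0,
                    region_end=region_end,
                    intron_len=i,
                    atg_start=a0,
                    acceptor_ok=acc_ok,
                    donor_ok=don_ok,
                    atg_ok=atg_ok,
                    leader_stop_free=not has_stop(leader),
                )
            )
    out.sort(key=lambda c: c.score(cfg), reverse=True)
    return out


# ---------------------------------------------------------------------------
# J-gene structural candidates
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class JCandidate:
    """A candidate J-REGION on a sense window starting at the heptamer end.

    ``region_len`` is the distance from the heptamer to the GT donor; the
    J-REGION frame is taken to start immediately after the heptamer.
    """

    region_len: int
    has_motif: bool
    in_frame: bool

    def score(self, cfg: StructureConfig):
        return (
            2 * int(self.has_motif) + int(self.in_frame),
            -abs(self.region_len - cfg.pref_j_region),
            -self.region_len,
        )


def j_structure_candidates(
    sense_after_heptamer: str, cfg: StructureConfig | None = None
) -> list[JCandidate]:
    """Enumerate J-REGIONs ending at a GT donor, best-first.

    The hallmark FGXG motif and an in-frame (multiple-of-three) region are
    scored but not required, so ORF (motif-less) and pseudogene J genes are
    still delimited.
    """
    cfg = cfg or StructureConfig()
    out = []
    for L in range(cfg.min_j_region, cfg.max_j_region + 1):
        if len(sense_after_heptamer) < L + 2:
            break
        if sense_after_heptamer[L : L + 2] != "GT":
            continue
        aa = translate(sense_after_heptamer[:L])
        out.append(
            JCandidate(
                region_len=L,
                has_motif=FGXG_RE.search(aa) is not None,
                in_frame=L % 3 == 0,
            )
        )
    out.sort(key=lambda c: c.score(cfg), reverse=True)
    return out


# ---------------------------------------------------------------------------
# D-gene pairing
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DSegment:
    """A D gene delimited by a 5'D-RS / 3'D-RS pair.

    ``region`` is the forward-strand genomic interval of the D-REGION;
    ``strand`` the coding strand.
    """

    strand: str
    region: tuple[int, int]
    d5: RSHit
    d3: RSHit

    def span(self) -> tuple[int, int]:
        lo = min(self.d5.span()[0], self.d3.span()[0])
        hi = max(self.d5.span()[1], self.d3.span()[1])
        return lo, hi


def pair_d_hits(
    hits12: list[RSHit], hits23: list[RSHit], cfg: StructureConfig | None = None
) -> list[DSegment]:
    """Pair 12-spacer and 23-spacer hits flanking a plausible D-REGION.

    For a D gene on strand ``t`` the 5'D-RS motif reads canonically on the
    opposite strand and the 3'D-RS on ``t`` itself; the two heptamer flanks
    delimit the D-REGION.  Unpaired hits are simply not emitted as D genes.
    """
    cfg = cfg or StructureConfig()
    pairs: list[DSegment] = []
    for h5 in hits12:
        t = h5.coding_strand
        for h3 in hits23:
            if h3.strand != t:
                continue
            if t == "+":
                start, end = h5.flank, h3.flank
            else:
                start, end = h3.flank, h5.flank
            gap = end - start
            if cfg.min_d_region <= gap <= cfg.max_d_region:
                pairs.append(DSegment(t, (start, end), h5, h3))
    # deterministic de-duplication: smallest D first, each hit used once
    pairs.sort(key=lambda d: (d.region[1] - d.region[0], d.region[0]))
    used: set[tuple[int, int]] = set()
    out = []
    for d in pairs:
        k5, k3 = d.d5.heptamer, d.d3.heptamer
        if k5 in used or k3 in used:
            continue
        used.add(k5)
        used.add(k3)
        out.append(d)
    out.sort(key=lambda d: d.region[0])
    return out
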