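"""Germline V/J/D/C gene discovery in genomic sequence.

The annotation strategy mirrors manual TR locus curation: constant genes are
localised first from cDNA queries (they also define the locus orientation),
then RS motifs are scanned genome-wide and each hit is tested against the
structural gene grammar of :mod:`tralocus.genemodel` — V genes must present a
leader/intron/L-PART2/V-REGION chain upstream of a 23-spacer RS, J genes a
J-REGION running from a 12-spacer RS to a GT donor, and D genes a short
region flanked by a 12/23 RS pair.  Functionality follows the IMGT-style
F / ORF / P classes: stop codons or frameshifts make a pseudogene; splice,
RS or J-motif defects make an ORF; everything else is functional.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import edlib

from ._seq import has_stop, revcomp, translate
from .genemodel import (
    FGXG_RE,
    RSConfig,
    RSHit,
    StructureConfig,
    j_structure_candidates,
    pair_d_hits,
    scan_rs,
    v_structure_candidates,
)
from .numbering import NumberedVDomain, NumberingError, imgt_number_v
from .records import ConstantGeneModel, GeneAnnotation, write_gene_fasta, write_gff3

log = logging.getLogger(__name__)


@dataclass
class AnnotationConfig:
    """All tunables of the annotator.

    ``strict_conserved`` demotes F to ORF on a missing conserved residue even
    when splice and RS evidence is perfect (off by default: a substitution of
    the 1st-CYS alone does not mechanically imply a non-functional gene).
    """

    rs: RSConfig = field(default_factory=RSConfig)
    structure: StructureConfig = field(default_factory=StructureConfig)
    strict_conserved: bool = False
    c_seed_len: int = 30
    c_seed_max_dist: int = 2
    c_max_mismatches: int = 8
    c_identity_floor: float = 90.0


def classify_functionality(
    defects, gene_type: str = "V", chain: str = "TRA", strict_conserved: bool = False
) -> str:
    """Deterministic defect-to-class mapping (F / ORF / P).

    Stop codons and frameshifts always give P.  Splice or RS defects give
    ORF, as does a missing FGXG motif in a TRAJ gene — the single salmonid
    TRDJ carries an FGKA variant motif and is exempted.  A missing conserved
    residue demotes to ORF only under ``strict_conserved``.
    """
    d = set(defects)
    if "stop_codon" in d or "frameshift" in d:
        return "P"
    if "splice_defect" in d or "rs_defect" in d:
        return "ORF"
    if "missing_FGXG" in d and gene_type == "J" and chain == "TRA":
        return "ORF"
    if "missing_conserved_residue" in d and strict_conserved:
        return "ORF"
    return "F"


# ---------------------------------------------------------------------------
# Constant genes
# ---------------------------------------------------------------------------


def _spliced_walk(s: str, q: str, i0: int, intron_rng: tuple[int, int], max_mm: int):
    """Greedily thread query ``q`` through ``s`` from ``i0`` across GT..AG
    introns; returns (exon intervals, mismatches) or None."""
    i, j = i0, 0
    exon_start = i
    exons: list[tuple[int, int]] = []
    mm = 0
    L = len(q)
    while j < L:
        if i >= len(s):
            return None
        if s[i : i + 2] == "GT" and j <= L - 12 and s[i : i + 12] != q[j : j + 12]:
            jumped = False
            for t in range(intron_rng[0], intron_rng[1] + 1):
                if s[i + t - 2 : i + t] == "AG" and s[i + t : i + t + 12] == q[j : j + 12]:
                    exons.append((exon_start, i))
                    i += t
                    exon_start = i
                    jumped = True
                    break
            if jumped:
                continue
        if s[i] != q[j]:
            mm += 1
            if mm > max_mm:
                return None
        i += 1
        j += 1
    exons.append((exon_start, i))
    return exons, mm


def find_constant_genes(
    genome: str, c_queries: dict[str, str], cfg: AnnotationConfig | None = None,
    contig: str = "contig",
) -> list[ConstantGeneModel]:
    """Localise constant genes from spliced cDNA queries.

    Each query is seeded with edlib and extended exon by exon across GT..AG
    introns.  Queries without a hit above the identity floor are skipped with
    a warning; the strand of the models defines the locus orientation.
    """
    cfg = cfg or AnnotationConfig()
    intron_rng = (cfg.structure.min_c_intron, cfg.structure.max_c_intron)
    models = []
    for qid, q in c_queries.items():
        best = None
        for strand in "+-":
            s = genome if strand == "+" else revcomp(genome)
            res = edlib.align(q[: cfg.c_seed_len], s, mode="HW", task="locations",
                              k=cfg.c_seed_max_dist)
            if res["editDistance"] < 0:
                continue
            starts = sorted({loc[0] for loc in res["locations"]})[:25]
            for st in starts:
                walk = _spliced_walk(s, q, st, intron_rng, cfg.c_max_mismatches)
                if walk is None:
                    continue
                exons_local, mm = walk
                if best is None or mm < best[2]:
                    best = (strand, exons_local, mm)
        if best is None:
            log.warning("constant-gene query %s: no hit above identity floor", qid)
            continue
        strand, exons_local, mm = best
        identity = 100.0 * (len(q) - mm) / len(q)
        if identity < cfg.c_identity_floor:
            log.warning("constant-gene query %s: best identity %.1f below floor",
                        qid, identity)
            continue
        n = len(genome)
        if strand == "+":
            exons = list(exons_local)  # already in transcription order
        else:
            exons = [(n - b, n - a) for a, b in exons_local]
        gseq = "".join(genome[a:b] for a, b in sorted(exons))
        if strand == "-":
            gseq = revcomp(gseq)
        aa = translate(gseq)
        translated_len = aa.index("*") if "*" in aa else len(aa)
        chain = "TRA" if "TRAC" in qid.upper() else ("TRD" if "TRDC" in qid.upper() else qid)
        models.append(
            ConstantGeneModel(
                contig=contig,
                strand=strand,
                exons=exons,
                query_id=qid,
                percent_identity=identity,
                translated_len=translated_len,
                splice_ok="*" not in aa[:translated_len],
                chain=chain,
            )
        )
    return models


# ---------------------------------------------------------------------------
# V / J / D genes
# ---------------------------------------------------------------------------


def _rs_parts(h: RSHit, prefix: str) -> dict[str, tuple[int, int]]:
    lo = min(h.heptamer[1], h.nonamer[1])
    hi = max(h.heptamer[0], h.nonamer[0])
    return {
        f"{prefix}-HEPTAMER": h.heptamer,
        f"{prefix}-SPACER": (lo, hi),
        f"{prefix}-NONAMER": h.nonamer,
    }


def _rs_defective(h: RSHit, rs: RSConfig) -> bool:
    return h.heptamer_mm > rs.functional_heptamer_mm or h.nonamer_mm > rs.functional_nonamer_mm


def annotate_v_genes(
    genome: str, hits: list[RSHit], cfg: AnnotationConfig | None = None,
    contig: str = "contig",
) -> list[GeneAnnotation]:
    """Delimit V genes upstream of 23-spacer RS hits.

    For each hit the best-scoring leader/intron/L-PART2/V-REGION structure is
    taken (see :func:`tralocus.genemodel.v_structure_candidates`); hits with
    no viable structure are discarded.  Overlapping candidates from different
    hits are resolved by fewest RS mismatches, then longest V-REGION, then
    leftmost position.
    """
    cfg = cfg or AnnotationConfig()
    st = cfg.structure
    out: list[tuple[GeneAnnotation, RSHit]] = []
    for h in hits:
        strand = h.strand
        if strand == "+":
            h0 = h.heptamer[0]
            w0 = max(0, h0 - st.max_v_span - 8)
            sense = genome[w0:h0]

            def conv(a, b, w0=w0):
                return (w0 + a, w0 + b)

        else:
            h1 = h.heptamer[1]
            w1 = min(len(genome), h1 + st.max_v_span + 8)
            sense = revcomp(genome[h1:w1])

            def conv(a, b, w1=w1):
                return (w1 - b, w1 - a)

        cands = v_structure_candidates(sense, len(sense), st)
        if not cands:
            log.debug("V-RS hit at %s: no viable V structure", h.heptamer)
            continue
        c = cands[0]
        parts = {name: conv(*iv) for name, iv in c.parts(st).items()}
        parts.update(_rs_parts(h, "V"))
        region = sense[c.region_start :]
        leader = (
            sense[c.atg_start : c.atg_start + st.l_part1_len]
            + sense[c.region_start - st.l_part2_len : c.region_start]
        )
        defects: list[str] = []
        notes: dict = {"heptamer_mm": h.heptamer_mm, "nonamer_mm": h.nonamer_mm}
        if not (c.acceptor_ok and c.donor_ok and c.atg_ok):
            defects.append("splice_defect")
        if _rs_defective(h, cfg.rs):
            defects.append("rs_defect")
        if c.region_len % 3:
            defects.append("frameshift")
        elif has_stop(leader + region):
            defects.append("stop_codon")
        numbering: NumberedVDomain | None = None
        if "frameshift" not in defects and "stop_codon" not in defects:
            try:
                numbering = imgt_number_v(translate(region))
                notes["cdr_triplet"] = numbering.triplet
                notes["cdr_lengths"] = numbering.cdr_lengths
                if not numbering.has_conserved_triad:
                    defects.append("missing_conserved_residue")
            except NumberingError:
                notes["numbering_failed"] = True
        func = classify_functionality(defects, "V", "TRA", cfg.strict_conserved)
        span_lo = min(p[0] for p in parts.values())
        span_hi = max(p[1] for p in parts.values())
        ann = GeneAnnotation(
            gene_type="V",
            chain="TRA",
            contig=contig,
            start=span_lo,
            end=span_hi,
            strand=strand,
            parts=parts,
            functionality=func,
            defects=tuple(defects),
            notes=notes,
        )
        out.append((ann, h))
    # resolve overlaps deterministically
    out.sort(key=lambda ah: (ah[1].total_mm, -(
        ah[0].parts["V-REGION"][1] - ah[0].parts["V-REGION"][0]), ah[0].start))
    kept: list[GeneAnnotation] = []
    for ann, _h in out:
        if any(k.strand == ann.strand and k.start < ann.end and ann.start < k.end
               for k in kept):
            continue
        kept.append(ann)
    kept.sort(key=lambda a: a.start)
    return kept


def annotate_j_genes(
    genome: str, hits: list[RSHit], windows: dict[str, tuple[int, int]],
    cfg: AnnotationConfig | None = None, contig: str = "contig",
) -> list[GeneAnnotation]:
    """Delimit J genes downstream of 12-spacer RS hits inside the cluster.

    ``windows`` maps chain labels (TRA, TRD) to genomic intervals; a hit is
    assigned to the window containing its heptamer.  Each J spans its RS
    through the J-REGION, which ends at the best-scoring GT donor; the FGXG
    hallmark motif is recorded and its absence demotes TRAJ genes to ORF.
    """
    cfg = cfg or AnnotationConfig()
    st = cfg.structure
    out = []
    for h in hits:
        mid = (h.heptamer[0] + h.heptamer[1]) // 2
        chain = next((c for c, (a, b) in windows.items() if a <= mid < b), None)
        if chain is None:
            continue
        if h.strand == "+":
            a = h.heptamer[0]
            sense = revcomp(genome[max(0, a - st.max_j_region - 2) : a])
            coding_strand = "-"
        else:
            b = h.heptamer[1]
            sense = genome[b : b + st.max_j_region + 2]
            coding_strand = "+"
        cands = j_structure_candidates(sense, st)
        if not cands:
            log.debug("J-RS hit at %s: no donor splice within range", h.heptamer)
            continue
        L = cands[0].region_len
        if h.strand == "+":
            region_iv = (h.heptamer[0] - L, h.heptamer[0])
            donor_iv = (region_iv[0] - 2, region_iv[0])
        else:
            region_iv = (h.heptamer[1], h.heptamer[1] + L)
            donor_iv = (region_iv[1], region_iv[1] + 2)
        region = sense[:L]
        aa = translate(region)
        defects = []
        notes: dict = {"heptamer_mm": h.heptamer_mm, "nonamer_mm": h.nonamer_mm,
                       "j_aa": aa}
        if not FGXG_RE.search(aa):
            defects.append("missing_FGXG")
        if _rs_defective(h, cfg.rs):
            defects.append("rs_defect")
        if L % 3:
            defects.append("frameshift")
        elif "*" in aa:
            defects.append("stop_codon")
        func = classify_functionality(defects, "J", chain, cfg.strict_conserved)
        parts = {"J-REGION": region_iv, "DONOR": donor_iv}
        parts.update(_rs_parts(h, "J"))
        span_lo = min(region_iv[0], h.nonamer[0], h.heptamer[0])
        span_hi = max(region_iv[1], h.nonamer[1], h.heptamer[1])
        out.append(
            GeneAnnotation(
                gene_type="J",
                chain=chain,
                contig=contig,
                start=span_lo,
                end=span_hi,
                strand=coding_strand,
                parts=parts,
                functionality=func,
                defects=tuple(defects),
                notes=notes,
            )
        )
    out.sort(key=lambda a: a.start)
    return out


def annotate_d_genes(
    genome: str, hits12: list[RSHit], hits23: list[RSHit],
    cfg: AnnotationConfig | None = None, contig: str = "contig",
) -> tuple[list[GeneAnnotation], set]:
    """Pair 5'D/3'D RS hits into D genes.

    Returns the annotations and the set of heptamer intervals consumed by D
    pairing, so V/J annotation can ignore those hits.  A stop codon in any of
    the three D-REGION frames is recorded as a note (the gene is still
    emitted).
    """
    cfg = cfg or AnnotationConfig()
    segs = pair_d_hits(hits12, hits23, cfg.structure)
    out = []
    used = set()
    for d in segs:
        used.add(d.d5.heptamer)
        used.add(d.d3.heptamer)
        region = genome[d.region[0] : d.region[1]]
        if d.strand == "-":
            region = revcomp(region)
        frames_open = [not has_stop(region[f:]) for f in range(3)]
        defects = []
        if _rs_defective(d.d5, cfg.rs) or _rs_defective(d.d3, cfg.rs):
            defects.append("rs_defect")
        parts = {"D-REGION": d.region}
        parts.update(_rs_parts(d.d5, "D5"))
        parts.update(_rs_parts(d.d3, "D3"))
        span = d.span()
        out.append(
            GeneAnnotation(
                gene_type="D",
                chain="TRD",
                contig=contig,
                start=span[0],
                end=span[1],
                strand=d.strand,
                parts=parts,
                functionality=classify_functionality(defects, "D", "TRD"),
                defects=tuple(defects),
                notes={"frames_open": frames_open,
                       "d_length": d.region[1] - d.region[0]},
            )
        )
    return out, used


# ---------------------------------------------------------------------------
# Whole-locus orchestration
# ---------------------------------------------------------------------------


@dataclass
class LocusAnnotation:
    """Everything the annotator found on one contig."""

    contig: str
    genome: str
    c_models: list[ConstantGeneModel]
    genes: list[GeneAnnotation]  # V, J, D and C annotations
    orientation: str  # REV if C genes transcribe right-to-left on the contig

    def of_type(self, gene_type: str, chain: str | None = None):
        return [g for g in self.genes
                if g.gene_type == gene_type and (chain is None or g.chain == chain)]

    def locus_order(self) -> list[GeneAnnotation]:
        """Genes sorted along the locus 5'->3' (defined by C orientation)."""
        rev = self.orientation == "REV"
        return sorted(self.genes, key=lambda g: -g.start if rev else g.start)


def _j_windows(c_models: list[ConstantGeneModel], n: int) -> dict[str, tuple[int, int]]:
    trac = next((m for m in c_models if m.chain == "TRA"), None)
    trdc = next((m for m in c_models if m.chain == "TRD"), None)
    windows: dict[str, tuple[int, int]] = {}
    if trac and trdc:
        lo = min(trac.end, trdc.end)
        hi = max(trac.start, trdc.start)
        if lo < hi:
            windows["TRA"] = (lo, hi)
        if trdc.start > trac.start:
            windows["TRD"] = (trdc.end, n)
        else:
            windows["TRD"] = (0, trdc.start)
    elif trdc:
        windows["TRD"] = (0, n)
    elif trac:
        windows["TRA"] = (0, n)
    return windows


def annotate_locus(
    genome: str, c_queries: dict[str, str], cfg: AnnotationConfig | None = None,
    contig: str = "contig",
) -> LocusAnnotation:
    """Run the full annotation cascade on one contig.

    Constant genes are found first (locus orientation and J windows), then D
    genes are paired, and remaining RS hits are interpreted as V and J genes.
    """
    cfg = cfg or AnnotationConfig()
    c_models = find_constant_genes(genome, c_queries, cfg, contig=contig)
    hits23 = scan_rs(genome, "V", config=cfg.rs)
    hits12 = scan_rs(genome, "J", config=cfg.rs)
    d_anns, used = annotate_d_genes(genome, hits12, hits23, cfg, contig=contig)
    hits23 = [h for h in hits23 if h.heptamer not in used]
    hits12 = [h for h in hits12 if h.heptamer not in used]
    v_anns = annotate_v_genes(genome, hits23, cfg, contig=contig)
    windows = _j_windows(c_models, len(genome))
    j_anns = annotate_j_genes(genome, hits12, windows, cfg, contig=contig)
    strands = [m.strand for m in c_models]
    orientation = "REV" if strands.count("-") >= max(1, len(strands) - strands.count("-")) else "FWD"
    genes = v_anns + j_anns + d_anns + [m.to_annotation() for m in c_models]
    genes.sort(key=lambda g: g.start)
    log.info(
        "annotated %d V, %d J, %d D, %d C genes (orientation %s)",
        len(v_anns), len(j_anns), len(d_anns), len(c_models), orientation,
    )
    return LocusAnnotation(
        contig=contig, genome=genome, c_models=c_models, genes=genes,
        orientation=orientation,
    )


def write_annotation(
    annotation: LocusAnnotation, outdir: str | Path,
) -> dict[str, Path]:
    """Emit GFF3, per-class FASTA and a census TSV for an annotated locus."""
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["gff3"] = outdir / "annotation.gff3"
    write_gff3(annotation.genes, paths["gff3"])
    for gene_type in "VJDC":
        anns = annotation.of_type(gene_type)
        if anns:
            p = outdir / f"{gene_type}_genes.fasta"
            write_gene_fasta(anns, annotation.genome, p)
            paths[f"{gene_type}_fasta"] = p
    v_regions = [g for g in annotation.of_type("V") if "V-REGION" in g.parts]
    if v_regions:
        paths["v_regions"] = outdir / "V_regions.fasta"
        write_gene_fasta(v_regions, annotation.genome, paths["v_regions"], part="V-REGION")
    rows = []
    by_sg: dict[int, list[GeneAnnotation]] = {}
    for g in annotation.of_type("V"):
        if g.functionality in ("F", "ORF") and g.subgroup is not None:
            by_sg.setdefault(g.subgroup, []).append(g)
    for sg in sorted(by_sg):
        members = by_sg[sg]
        triplets = sorted({m.notes.get("cdr_triplet", "?") for m in members})
        rows.append(
            {
                "subgroup": f"TRAV{sg}",
                "n_F": sum(m.functionality == "F" for m in members),
                "n_ORF": sum(m.functionality == "ORF" for m in members),
                "cdr_lengths": " ".join(triplets),
            }
        )
    paths["census"] = outdir / "subgroup_census.tsv"
    pd.DataFrame(rows, columns=["subgroup", "n_F", "n_ORF", "cdr_lengths"]).to_csv(
        paths["census"], sep="\t", index=False
    )
    return paths
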