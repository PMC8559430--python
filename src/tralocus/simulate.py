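"""Ground-truthed synthetic TRA/TRD loci and 5'-RACE repertoire reads.

The generator plants V, J, D and C genes with the architecture the annotator
searches for (see :mod:`tralocus.genemodel`): V genes carry an ATG-initiated
L-PART1, a GT..AG intron, an 11-nt L-PART2 and a V-REGION ending at a
canonical V-RS; J genes run from a J-RS through an FGXG-bearing J-REGION to a
GT donor; D genes sit between a 12-spacer 5'D-RS and a 23-spacer 3'D-RS; C
genes have three GT..AG-bounded exons encoding a 110-aa constant domain.

The chromosome follows the teleost layout: reading the forward strand, the V
array comes first (transcribed towards the cluster), then TRAC, the TRAJ
array, TRDC, TRDJ and the TRDD genes, all cluster genes in inverted
orientation.  The locus therefore reads 5'->3' from the TRDD end, and V gene
ranks count from the cluster-proximal end.

Because recovery tests demand exact coordinates, the generator *scrubs* the
assembled chromosome: any spurious RS motif, or any structural candidate that
would tie or outrank a planted gene under the annotator's deterministic
scoring, is destroyed by a point mutation in an unconstrained position.  The
scrub is part of the ground-truth contract (the analogue of the
identity-separation invariant), and is deterministic under the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._seq import AA_CODONS, STOP_CODONS, has_stop, revcomp, translate
from .genemodel import (
    FGXG_RE,
    HEPTAMER,
    NONAMER,
    RSConfig,
    StructureConfig,
    j_structure_candidates,
    pair_d_hits,
    scan_rs,
    v_structure_candidates,
)
from .numbering import (
    TEMPLATE_FR1,
    TEMPLATE_FR2,
    TEMPLATE_FR3,
)
from .records import GeneAnnotation

_BASES = "ACGT"
_CODONS = sorted(c for aa, cs in AA_CODONS.items() if aa != "*" for c in cs)

TRDJ_AA = "DKLTFGKAINLIVEP"  # conserved salmonid TRDJ with the FGKA variant motif
TRDD_BASE_LENGTHS = (8, 13, 14)

#: TRAC-anchored 5'RACE gene-specific primer (reverse orientation on the transcript)
GSP1_PRIMER = "GATTACGCCAAGCTTGGCAAGCTGTGGTATTGCTTGAGTTC"


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, n))


def _rand_coding(rng: np.random.Generator, n_codons: int) -> str:
    idx = rng.integers(0, len(_CODONS), n_codons)
    return "".join(_CODONS[i] for i in idx)


def _encode_aa(aa: str, rng: np.random.Generator) -> str:
    return "".join(AA_CODONS[a][rng.integers(0, len(AA_CODONS[a]))] for a in aa)


def _mutate_coding(
    seq: str, rate: float, rng: np.random.Generator, protected_codons: set[int]
) -> str:
    """Substitute bases at ``rate`` without creating stops or touching
    protected codons.  ``seq`` is in-frame coding sequence."""
    s = list(seq)
    hit = np.nonzero(rng.random(len(s)) < rate)[0]
    for p in hit.tolist():
        ci = p // 3
        if ci in protected_codons:
            continue
        alts = [b for b in _BASES if b != s[p]]
        rng.shuffle(alts)
        for b in alts:
            old = s[p]
            s[p] = b
            codon = "".join(s[ci * 3 : ci * 3 + 3])
            if codon not in STOP_CODONS:
                break
            s[p] = old
    return "".join(s)


# ---------------------------------------------------------------------------
# Specifications
# ---------------------------------------------------------------------------


@dataclass
class LocusSpec:
    """Parameters of a synthetic TRA/TRD locus.

    ``within_subgroup_identity`` / ``between_subgroup_identity`` are target
    pairwise V-REGION nucleotide identities and must straddle the 75%
    subgroup threshold so that the planted subgroups are recoverable.
    ``inverted_block`` gives a 1-based inclusive range of V locus ranks
    placed in the cluster's orientation (the Atlantic-salmon inverted block).
    """

    n_subgroups: int = 8
    genes_per_subgroup: tuple[int, int] = (3, 7)
    within_subgroup_identity: float = 0.86
    between_subgroup_identity: float = 0.55
    pseudogene_fraction: float = 0.2
    orf_fraction: float = 0.1
    n_traj: int = 10
    n_trdd: int = 3
    intergenic_length_range: tuple[int, int] = (150, 400)
    inverted_block: tuple[int, int] | None = None
    rng_seed: int = 0

    def __post_init__(self):
        if isinstance(self.genes_per_subgroup, int):
            self.genes_per_subgroup = (self.genes_per_subgroup, self.genes_per_subgroup)

    def validate(self) -> None:
        w, b = self.within_subgroup_identity, self.between_subgroup_identity
        if not (w > 0.75 > b):
            raise ValueError(
                f"infeasible identity constraints: need within ({w}) > 0.75 > between ({b})"
            )
        if self.pseudogene_fraction + self.orf_fraction > 1:
            raise ValueError("pseudogene_fraction + orf_fraction must be <= 1")
        lo, hi = self.genes_per_subgroup
        if not (1 <= lo <= hi):
            raise ValueError("genes_per_subgroup must be a positive (lo, hi) range")
        if self.intergenic_length_range[0] < 60:
            raise ValueError("intergenic spacing below 60 bp risks overlapping features")


@dataclass
class RepertoireSpec:
    """Parameters of a simulated C-primed TR-alpha amplicon read set.

    ``usage_weights`` is a V x J matrix of sampling probabilities (uniform if
    None); ``productive_fraction`` is achieved exactly by junction frame
    control, not by rejection.  Sequencing noise is substitution-only and
    qualities are constant (the pipeline never uses them).
    """

    usage_weights: np.ndarray | None = None
    n_reads: int = 2000
    productive_fraction: float = 0.8
    junction_trim_max: int = 6
    n_addition_max: int = 6
    read_length: int = 250
    substitution_error_rate: float = 0.0
    c_primer_offset: int = 60
    rng_seed: int = 0


# ---------------------------------------------------------------------------
# Gene records
# ---------------------------------------------------------------------------


@dataclass
class SimGene:
    """A planted germline gene: sense-strand sequence, parts and truth labels."""

    gene_type: str
    chain: str
    functionality: str
    defects: tuple[str, ...]
    seq: str
    parts: dict[str, tuple[int, int]]
    span_local: tuple[int, int]
    subgroup: int | None = None
    meta: dict = field(default_factory=dict)
    name: str | None = None
    strand: str | None = None
    offset: int | None = None

    def genomic(self, local: tuple[int, int]) -> tuple[int, int]:
        a, b = local
        n = len(self.seq)
        if self.strand == "+":
            return (self.offset + a, self.offset + b)
        return (self.offset + n - b, self.offset + n - a)

    @property
    def start(self) -> int:
        return self.genomic(self.span_local)[0]

    @property
    def end(self) -> int:
        return self.genomic(self.span_local)[1]

    def part_seq(self, part: str) -> str:
        a, b = self.parts[part]
        return self.seq[a:b]

    @property
    def leader_seq(self) -> str:
        return self.part_seq("L-PART1") + self.part_seq("L-PART2")

    def refresh_from(self, genome: str) -> None:
        """Re-extract the sense sequence after chromosome-level scrubbing."""
        a, b = self.offset, self.offset + len(self.seq)
        s = genome[a:b]
        self.seq = s if self.strand == "+" else revcomp(s)

    def to_annotation(self, contig: str) -> GeneAnnotation:
        parts = {p: self.genomic(iv) for p, iv in self.parts.items()}
        return GeneAnnotation(
            gene_type=self.gene_type,
            chain=self.chain,
            contig=contig,
            start=self.start,
            end=self.end,
            strand=self.strand,
            parts=parts,
            functionality=self.functionality,
            defects=self.defects,
            name=self.name,
            subgroup=self.subgroup,
        )


@dataclass
class GermlineSet:
    """The planted germline gene set (ground truth before locus assembly)."""

    genes: list[SimGene]
    spec: LocusSpec

    def of_type(self, gene_type: str, chain: str | None = None) -> list[SimGene]:
        return [
            g
            for g in self.genes
            if g.gene_type == gene_type and (chain is None or g.chain == chain)
        ]

    def functional(self, gene_type: str, chain: str | None = None) -> list[SimGene]:
        return [g for g in self.of_type(gene_type, chain) if g.functionality == "F"]


# ---------------------------------------------------------------------------
# Germline gene construction
# ---------------------------------------------------------------------------

_FR_AA = (TEMPLATE_FR1, TEMPLATE_FR2, TEMPLATE_FR3)
# protected codon indices within each framework block (1st-CYS 23, Trp 41, 2nd-CYS 104)
_FR_PROTECT = ({22}, {2}, {38})


def _build_v_region(
    rng: np.random.Generator,
    fr_roots: tuple[str, str, str],
    between_rate: float,
    cdr: tuple[int, int, int],
) -> tuple[str, tuple[int, int, int]]:
    """Subgroup-ancestor V-REGION: mutated framework roots + fresh CDR codons."""
    frs = [
        _mutate_coding(root, between_rate, rng, prot)
        for root, prot in zip(fr_roots, _FR_PROTECT)
    ]
    c1, c2, c3 = cdr
    region = (
        frs[0]
        + _rand_coding(rng, c1)
        + frs[1]
        + _rand_coding(rng, c2)
        + frs[2]
        + _rand_coding(rng, c3)
    )
    return region, cdr


def _v_protected_codons(cdr: tuple[int, int, int]) -> set[int]:
    c1, c2, _ = cdr
    return {22, 26 + c1 + 2, 26 + c1 + 17 + c2 + 38}


def _make_v_gene(
    rng: np.random.Generator,
    leader_root: str,
    ancestor_region: str,
    cdr: tuple[int, int, int],
    member_rate: float,
    subgroup: int,
) -> SimGene:
    region = _mutate_coding(ancestor_region, member_rate, rng, _v_protected_codons(cdr))
    leader = "ATG" + _mutate_coding(leader_root[3:], 0.02, rng, set())
    lp1, lp2 = leader[:37], leader[37:]
    intron_len = int(rng.integers(85, 116))
    intron = "GT" + _rand_seq(rng, intron_len - 4) + "AG"
    spacer = _rand_seq(rng, 22)
    seq = lp1 + intron + lp2 + region + HEPTAMER + spacer + NONAMER
    p = 0
    parts = {}
    for part, ln in (
        ("L-PART1", 37),
        ("V-INTRON", intron_len),
        ("L-PART2", 11),
        ("V-REGION", len(region)),
        ("V-HEPTAMER", 7),
        ("V-SPACER", 22),
        ("V-NONAMER", 9),
    ):
        parts[part] = (p, p + ln)
        p += ln
    c1, c2, _ = cdr
    return SimGene(
        gene_type="V",
        chain="TRA",
        functionality="F",
        defects=(),
        seq=seq,
        parts=parts,
        span_local=(0, len(seq)),
        subgroup=subgroup,
        meta={"cdr": cdr, "c104_codon": 26 + c1 + 17 + c2 + 38},
    )


def _plant_v_defect(gene: SimGene, kind: str, rng: np.random.Generator) -> None:
    """Give a V gene exactly one planted defect class and relabel it."""
    s = list(gene.seq)
    r0, r1 = gene.parts["V-REGION"]
    protected = {r0 + 3 * c + k for c in _v_protected_codons(gene.meta["cdr"]) for k in range(3)}
    if kind == "stop_codon":
        while True:
            ci = int(rng.integers(1, (r1 - r0) // 3 - 1))
            pos = r0 + 3 * ci
            if pos not in protected:
                break
        stop = ["TAA", "TAG", "TGA"][rng.integers(0, 3)]
        s[pos : pos + 3] = stop
        gene.meta["planted_stop"] = (pos, pos + 3)
        gene.functionality, gene.defects = "P", ("stop_codon",)
    elif kind == "frameshift":
        while True:
            pos = int(rng.integers(r0 + 3, r1 - 4))
            if pos not in protected:
                break
        del s[pos]
        gene.functionality, gene.defects = "P", ("frameshift",)
    elif kind == "rs_defect":
        if rng.random() < 0.5:
            h0, _ = gene.parts["V-HEPTAMER"]
            pos = h0 + int(rng.integers(3, 7))  # keep the CAC core detectable
            s[pos] = [b for b in _BASES if b != s[pos]][rng.integers(0, 3)]
        else:
            n0, _ = gene.parts["V-NONAMER"]
            for off in rng.choice(9, size=2, replace=False):
                pos = n0 + int(off)
                s[pos] = [b for b in _BASES if b != s[pos]][rng.integers(0, 3)]
        gene.functionality, gene.defects = "ORF", ("rs_defect",)
    elif kind == "splice_defect":
        # the donor GT is mutated; a broken acceptor would leave the V-REGION
        # 5' limit structurally unpinned, so the generator does not plant it
        i0, _ = gene.parts["V-INTRON"]
        s[i0 + 1] = "AC"[rng.integers(0, 2)]  # GT -> GA or GC
        gene.functionality, gene.defects = "ORF", ("splice_defect",)
    else:  # pragma: no cover
        raise ValueError(kind)
    new = "".join(s)
    if kind == "frameshift":
        # the V-REGION and everything downstream shrink by one base
        shrunk = {}
        for part, (a, b) in gene.parts.items():
            if part == "V-REGION":
                shrunk[part] = (a, b - 1)
            elif a >= gene.parts["V-REGION"][1]:
                shrunk[part] = (a - 1, b - 1)
            else:
                shrunk[part] = (a, b)
        gene.parts = shrunk
        gene.span_local = (0, len(new))
    gene.seq = new


def _make_j_gene(rng: np.random.Generator, chain: str) -> SimGene:
    if chain == "TRD":
        region = _encode_aa(TRDJ_AA, rng)
        motif_codon0 = 4  # FGKA starts at residue 5
        expect_motif = False
        defects = ("missing_FGXG",)
    else:
        while True:
            aa_x = "ACDEHIKLMNPQRSTVY"[rng.integers(0, 17)]
            region = (
                _rand_coding(rng, 8)
                + _encode_aa("FG" + aa_x + "G", rng)
                + _rand_coding(rng, 5)
            )
            aa = translate(region)
            if len(FGXG_RE.findall(aa)) == 1 and aa.index(
                FGXG_RE.search(aa).group()
            ) == 8:
                break
        motif_codon0 = 8
        expect_motif = True
        defects = ()
    spacer = _rand_seq(rng, 12)
    seq = revcomp(NONAMER) + spacer + revcomp(HEPTAMER) + region + "GT"
    p = 0
    parts = {}
    for part, ln in (
        ("J-NONAMER", 9),
        ("J-SPACER", 12),
        ("J-HEPTAMER", 7),
        ("J-REGION", len(region)),
        ("DONOR", 2),
    ):
        parts[part] = (p, p + ln)
        p += ln
    return SimGene(
        gene_type="J",
        chain=chain,
        functionality="F",
        defects=defects,
        seq=seq,
        parts=parts,
        span_local=(0, len(seq) - 2),  # span runs RS through J-REGION
        meta={"motif_codon0": motif_codon0, "expect_motif": expect_motif},
    )


def _plant_j_defect(gene: SimGene, kind: str, rng: np.random.Generator) -> None:
    s = list(gene.seq)
    r0, r1 = gene.parts["J-REGION"]
    m0 = gene.meta["motif_codon0"]
    if kind == "stop_codon":
        choices = [c for c in range(0, (r1 - r0) // 3) if not (m0 <= c < m0 + 4)]
        ci = choices[rng.integers(0, len(choices))]
        s[r0 + 3 * ci : r0 + 3 * ci + 3] = ["TAA", "TAG", "TGA"][rng.integers(0, 3)]
        gene.meta["planted_stop"] = (r0 + 3 * ci, r0 + 3 * ci + 3)
        gene.functionality, gene.defects = "P", ("stop_codon",)
    elif kind == "missing_FGXG":
        while True:
            aa = "ACDEHIKLMNPQRSTVY"[rng.integers(0, 17)]
            s[r0 + 3 * (m0 + 1) : r0 + 3 * (m0 + 1) + 3] = _encode_aa(aa, rng)
            if not FGXG_RE.search(translate("".join(s[r0:r1]))):
                break
        gene.meta["expect_motif"] = False
        gene.functionality, gene.defects = "ORF", ("missing_FGXG",)
    else:  # pragma: no cover
        raise ValueError(kind)
    gene.seq = "".join(s)


def _make_d_gene(rng: np.random.Generator, length: int) -> SimGene:
    while True:
        region = _rand_seq(rng, length)
        if not any(has_stop(region[f:]) for f in range(3)):
            break
    sp5 = _rand_seq(rng, 12)
    sp3 = _rand_seq(rng, 23)
    seq = revcomp(NONAMER) + sp5 + revcomp(HEPTAMER) + region + HEPTAMER + sp3 + NONAMER
    p = 0
    parts = {}
    for part, ln in (
        ("D5-NONAMER", 9),
        ("D5-SPACER", 12),
        ("D5-HEPTAMER", 7),
        ("D-REGION", length),
        ("D3-HEPTAMER", 7),
        ("D3-SPACER", 23),
        ("D3-NONAMER", 9),
    ):
        parts[part] = (p, p + ln)
        p += ln
    return SimGene(
        gene_type="D",
        chain="TRD",
        functionality="F",
        defects=(),
        seq=seq,
        parts=parts,
        span_local=(0, len(seq)),
    )


def _make_c_gene(rng: np.random.Generator, chain: str) -> SimGene:
    cds = _rand_coding(rng, 110) + "TAA"
    ex = (cds[:120], cds[120:270], cds[270:])
    introns = ["GT" + _rand_seq(rng, int(rng.integers(85, 116)) - 4) + "AG" for _ in range(2)]
    seq = ex[0] + introns[0] + ex[1] + introns[1] + ex[2]
    p = 0
    parts = {}
    for part, ln in (
        ("EX1", 120),
        ("C-INTRON1", len(introns[0])),
        ("EX2", 150),
        ("C-INTRON2", len(introns[1])),
        ("EX3", 63),
    ):
        parts[part] = (p, p + ln)
        p += ln
    return SimGene(
        gene_type="C",
        chain=chain,
        functionality="F",
        defects=(),
        seq=seq,
        parts=parts,
        span_local=(0, len(seq)),
        name=chain + "C",
        meta={"cds": cds},
    )


def simulate_germline_set(spec: LocusSpec) -> GermlineSet:
    """Generate the planted germline gene set for a locus.

    V genes get their target within/between-subgroup nucleotide identities by
    mutating subgroup-ancestor V-REGIONs; pseudogene/ORF fractions are exact
    (rounded) counts, each non-functional gene carrying one defect class.
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    fr_roots = tuple(_encode_aa(fr, rng) for fr in _FR_AA)
    leader_root = "ATG" + _rand_coding(rng, 15)
    between_rate = (1 - spec.between_subgroup_identity) / 2
    member_rate = (1 - spec.within_subgroup_identity) / 2

    genes: list[SimGene] = []
    lo, hi = spec.genes_per_subgroup
    for sg in range(1, spec.n_subgroups + 1):
        cdr = (int(rng.integers(4, 10)), int(rng.integers(0, 11)), 3)
        ancestor, cdr = _build_v_region(rng, fr_roots, between_rate, cdr)
        for _ in range(int(rng.integers(lo, hi + 1))):
            genes.append(_make_v_gene(rng, leader_root, ancestor, cdr, member_rate, sg))

    n_v = len(genes)
    n_p = round(spec.pseudogene_fraction * n_v)
    n_orf = round(spec.orf_fraction * n_v)
    order = rng.permutation(n_v)
    p_kinds = ["stop_codon", "frameshift"]
    orf_kinds = ["rs_defect", "splice_defect"]
    for k, gi in enumerate(order[:n_p].tolist()):
        _plant_v_defect(genes[gi], p_kinds[k % 2], rng)
    for k, gi in enumerate(order[n_p : n_p + n_orf].tolist()):
        _plant_v_defect(genes[gi], orf_kinds[k % 2], rng)

    trajs = [_make_j_gene(rng, "TRA") for _ in range(spec.n_traj)]
    jn_p = round(spec.pseudogene_fraction * spec.n_traj)
    jn_orf = round(spec.orf_fraction * spec.n_traj)
    jorder = rng.permutation(spec.n_traj)
    for gi in jorder[:jn_p].tolist():
        _plant_j_defect(trajs[gi], "stop_codon", rng)
    for gi in jorder[jn_p : jn_p + jn_orf].tolist():
        _plant_j_defect(trajs[gi], "missing_FGXG", rng)

    trdj = _make_j_gene(rng, "TRD")
    d_lengths = list(TRDD_BASE_LENGTHS)
    while len(d_lengths) < spec.n_trdd:
        d_lengths.append(int(rng.integers(8, 17)))
    trdds = [_make_d_gene(rng, d_lengths[i]) for i in range(spec.n_trdd)]
    cs = [_make_c_gene(rng, "TRA"), _make_c_gene(rng, "TRD")]
    return GermlineSet(genes=genes + trajs + [trdj] + trdds + cs, spec=spec)


# ---------------------------------------------------------------------------
# Locus assembly and scrubbing
# ---------------------------------------------------------------------------

_FREE, _CODING, _IMMUT = 0, 1, 2


class _Chromosome:
    """Mutable chromosome with per-position constraint classes for scrubbing.

    A scrub mutation must not break a planted gene: positions are either
    free (intergenic, spacers, intron interiors), coding (mutable as long as
    the owning gene's spliced coding stays consistent with its planted
    functionality), or immutable (RS motifs, splice sites, start codons,
    conserved codons, planted defects, D-REGIONs).
    """

    def __init__(self, seq: str, rng: np.random.Generator):
        self.seq = bytearray(seq.encode())
        self.rng = rng
        self.cat = np.zeros(len(seq), dtype=np.uint8)
        self.gene_at: dict[int, SimGene] = {}

    def __str__(self) -> str:
        return self.seq.decode()

    def mark(self, interval: tuple[int, int], cat: int) -> None:
        self.cat[interval[0] : interval[1]] = cat

    def add_coding(self, interval: tuple[int, int], gene: SimGene) -> None:
        a, b = interval
        self.cat[a:b] = np.maximum(self.cat[a:b], _CODING)
        for p in range(a, b):
            self.gene_at[p] = gene

    def _sense(self, gene: SimGene, local: tuple[int, int]) -> str:
        a, b = gene.genomic(local)
        s = self.seq[a:b].decode()
        return s if gene.strand == "+" else revcomp(s)

    def _gene_ok(self, gene: SimGene) -> bool:
        """Does the gene's coding still honour its planted functionality?"""
        allow_stop = gene.functionality == "P"
        if gene.gene_type == "V":
            coding = (
                self._sense(gene, gene.parts["L-PART1"])
                + self._sense(gene, gene.parts["L-PART2"])
                + self._sense(gene, gene.parts["V-REGION"])
            )
            return allow_stop or not has_stop(coding)
        if gene.gene_type == "J":
            aa = translate(self._sense(gene, gene.parts["J-REGION"]))
            if not allow_stop and "*" in aa:
                return False
            return bool(FGXG_RE.search(aa)) == gene.meta.get("expect_motif", True)
        if gene.gene_type == "C":
            cds = "".join(self._sense(gene, gene.parts[p]) for p in ("EX1", "EX2", "EX3"))
            return "*" not in translate(cds[:-3])
        return True

    def try_mutate(self, p: int, forbid: str | None = None) -> bool:
        """Set position p to a base differing from both its current value and
        ``forbid`` (the motif consensus being destroyed), honouring constraints."""
        if p < 0 or p >= len(self.seq) or self.cat[p] == _IMMUT:
            return False
        cur = chr(self.seq[p])
        alts = [b for b in _BASES if b != cur and b != forbid]
        self.rng.shuffle(alts)
        if self.cat[p] == _FREE:
            self.seq[p] = ord(alts[0])
            return True
        gene = self.gene_at[p]
        for b in alts:
            self.seq[p] = ord(b)
            if self._gene_ok(gene):
                return True
        self.seq[p] = ord(cur)
        return False


@dataclass
class LocusSim:
    """A simulated chromosome plus its ground truth."""

    contig: str
    genome: str
    genes: list[SimGene]
    spec: LocusSpec

    def to_annotations(self) -> list[GeneAnnotation]:
        return [g.to_annotation(self.contig) for g in self.genes]

    def germline_set(self) -> GermlineSet:
        return GermlineSet(genes=self.genes, spec=self.spec)

    def c_queries(self) -> dict[str, str]:
        return {
            g.name: g.meta["cds"] for g in self.genes if g.gene_type == "C"
        }

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f">{self.contig}\n")
            for i in range(0, len(self.genome), 70):
                fh.write(self.genome[i : i + 70] + "\n")

    def write_truth_gff3(self, path: str | Path) -> None:
        from .records import write_gff3

        write_gff3(self.to_annotations(), path)


def _assign_locus_names(genes: list[SimGene]) -> None:
    """Truth names mirroring the nomenclature rules (rank along locus 5'->3').

    Subgroup numbers and ranks run over F/ORF genes only, as in the
    classifier (pseudogenes are not clustered); pseudogene V genes get
    placeholder names.
    """
    vs = [g for g in genes if g.gene_type == "V"]
    vs.sort(key=lambda g: -g.start)  # locus runs right to left on the chromosome
    fo = [g for g in vs if g.functionality in ("F", "ORF")]
    remap: dict[int, int] = {}
    for g in fo:
        if g.subgroup not in remap:
            remap[g.subgroup] = len(remap) + 1
    sizes: dict[int, int] = {}
    for g in fo:
        g.subgroup = remap[g.subgroup]
        sizes[g.subgroup] = sizes.get(g.subgroup, 0) + 1
    rank: dict[int, int] = {}
    for g in fo:
        rank[g.subgroup] = rank.get(g.subgroup, 0) + 1
        g.name = (
            f"TRAV{g.subgroup}"
            if sizes[g.subgroup] == 1
            else f"TRAV{g.subgroup}-{rank[g.subgroup]}"
        )
    for i, g in enumerate(g for g in vs if g.functionality == "P"):
        g.subgroup = None
        g.name = f"TRAVp{i + 1}"
    trajs = sorted((g for g in genes if g.gene_type == "J" and g.chain == "TRA"),
                   key=lambda g: g.start)
    for i, g in enumerate(trajs):  # TRAJ1 is the TRAC-proximal (leftmost) gene
        g.name = f"TRAJ{i + 1}"
    trdjs = sorted((g for g in genes if g.gene_type == "J" and g.chain == "TRD"),
                   key=lambda g: -g.start)
    for i, g in enumerate(trdjs):
        g.name = f"TRDJ{i + 1}"
    trdds = sorted((g for g in genes if g.gene_type == "D"), key=lambda g: -g.start)
    for i, g in enumerate(trdds):
        g.name = f"TRDD{i + 1}"


def _mark_constraints(chrom: _Chromosome, genes: list[SimGene]) -> None:
    for g in genes:
        if g.gene_type == "V":
            for part in ("L-PART1", "L-PART2", "V-REGION"):
                chrom.add_coding(g.genomic(g.parts[part]), g)
            i0, i1 = g.parts["V-INTRON"]
            for iv in ((i0, i0 + 2), (i1 - 2, i1)):  # splice dinucleotides
                chrom.mark(g.genomic(iv), _IMMUT)
            a0 = g.parts["L-PART1"][0]
            chrom.mark(g.genomic((a0, a0 + 3)), _IMMUT)  # ATG
            for part in ("V-HEPTAMER", "V-NONAMER"):
                chrom.mark(g.genomic(g.parts[part]), _IMMUT)
            r0 = g.parts["V-REGION"][0]
            for ci in sorted(_v_protected_codons(g.meta["cdr"])):
                iv = (r0 + 3 * ci, r0 + 3 * ci + 3)
                if iv[1] <= g.parts["V-REGION"][1]:
                    chrom.mark(g.genomic(iv), _IMMUT)
            if "planted_stop" in g.meta:
                chrom.mark(g.genomic(g.meta["planted_stop"]), _IMMUT)
        elif g.gene_type == "J":
            chrom.add_coding(g.genomic(g.parts["J-REGION"]), g)
            for part in ("J-HEPTAMER", "J-NONAMER", "DONOR"):
                chrom.mark(g.genomic(g.parts[part]), _IMMUT)
            r0 = g.parts["J-REGION"][0]
            m0 = g.meta["motif_codon0"]
            chrom.mark(g.genomic((r0 + 3 * m0, r0 + 3 * (m0 + 4))), _IMMUT)
            if "planted_stop" in g.meta:
                chrom.mark(g.genomic(g.meta["planted_stop"]), _IMMUT)
        elif g.gene_type == "D":
            # spacers stay free; the D-REGION and both motifs are fixed
            for part in ("D-REGION", "D5-HEPTAMER", "D5-NONAMER",
                         "D3-HEPTAMER", "D3-NONAMER"):
                chrom.mark(g.genomic(g.parts[part]), _IMMUT)
        elif g.gene_type == "C":
            for part in ("EX1", "EX2", "EX3"):
                chrom.add_coding(g.genomic(g.parts[part]), g)
            for part in ("C-INTRON1", "C-INTRON2"):
                i0, i1 = g.parts[part]
                chrom.mark(g.genomic((i0, i0 + 2)), _IMMUT)
                chrom.mark(g.genomic((i1 - 2, i1)), _IMMUT)
            c0, c1 = g.parts["EX3"]
            chrom.mark(g.genomic((c1 - 3, c1)), _IMMUT)  # terminal stop codon


def _expected_rs(genes: list[SimGene]):
    """Planted RS hits as (heptamer iv, nonamer iv, canonical strand) keys."""
    exp23, exp12 = set(), set()
    for g in genes:
        if g.gene_type == "V":
            opp = g.strand
            exp23.add((g.genomic(g.parts["V-HEPTAMER"]), g.genomic(g.parts["V-NONAMER"]), opp))
        elif g.gene_type == "J":
            opp = "-" if g.strand == "+" else "+"
            exp12.add((g.genomic(g.parts["J-HEPTAMER"]), g.genomic(g.parts["J-NONAMER"]), opp))
        elif g.gene_type == "D":
            opp = "-" if g.strand == "+" else "+"
            exp12.add((g.genomic(g.parts["D5-HEPTAMER"]), g.genomic(g.parts["D5-NONAMER"]), opp))
            exp23.add((g.genomic(g.parts["D3-HEPTAMER"]), g.genomic(g.parts["D3-NONAMER"]), g.strand))
    return exp23, exp12


def _v_truth_local(g: SimGene, window_len: int) -> tuple[int, int, int]:
    """(region_start, intron_len, atg_start) of the truth in window coords."""
    h0 = g.parts["V-HEPTAMER"][0]
    shift = window_len - h0
    i0, i1 = g.parts["V-INTRON"]
    return (g.parts["V-REGION"][0] + shift, i1 - i0, g.parts["L-PART1"][0] + shift)


_COMP1 = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _motif_targets(hit) -> list[tuple[int, str]]:
    """(genomic position, consensus base to avoid) pairs destroying an RS hit,
    CAC-core positions first (a single change there kills the match)."""
    out: list[tuple[int, str]] = []
    h0, h1 = hit.heptamer
    n0, n1 = hit.nonamer
    if hit.strand == "+":
        hept = [(h0 + k, HEPTAMER[k]) for k in range(7)]
        nona = [(n0 + k, NONAMER[k]) for k in range(9)]
        core, rest = hept[:3], hept[3:]
    else:
        hept = [(h1 - 1 - k, _COMP1[HEPTAMER[k]]) for k in range(7)]
        nona = [(n1 - 1 - k, _COMP1[NONAMER[k]]) for k in range(9)]
        core, rest = hept[:3], hept[3:]
    return core + rest + nona


def _scrub(chrom: _Chromosome, genes: list[SimGene],
           rs_cfg: RSConfig, st_cfg: StructureConfig, max_rounds: int = 60) -> bool:
    """Destroy spurious signals until the planted structure is unambiguous."""
    exp23, exp12 = _expected_rs(genes)
    exp_d = {(g.strand, g.genomic(g.parts["D-REGION"])) for g in genes if g.gene_type == "D"}
    vs = [g for g in genes if g.gene_type == "V"]
    js = [g for g in genes if g.gene_type == "J"]
    for _ in range(max_rounds):
        S = str(chrom)
        targets: list[list[tuple[int, str | None]]] = []
        hits23 = scan_rs(S, "V", config=rs_cfg)
        hits12 = scan_rs(S, "J", config=rs_cfg)
        for hits, exp in ((hits23, exp23), (hits12, exp12)):
            for h in hits:
                if (h.heptamer, h.nonamer, h.strand) not in exp:
                    # only positions still matching the consensus add a mismatch
                    targets.append(
                        [(p, f) for p, f in _motif_targets(h) if S[p] == f]
                    )
        rs_pending = bool(targets)
        if not rs_pending and (
            {(d.strand, d.region) for d in pair_d_hits(hits12, hits23, st_cfg)} != exp_d
        ):
            return False  # planted RS geometry broken: rebuild the locus
        for g in vs:
            h0g = g.genomic(g.parts["V-HEPTAMER"])[0 if g.strand == "+" else 1]
            if g.strand == "+":
                w0 = max(0, h0g - st_cfg.max_v_span - 8)
                sense = S[w0:h0g]

                def to_g(x, c, w0=w0):
                    return (w0 + x, c)

            else:
                w1 = min(len(S), h0g + st_cfg.max_v_span + 8)
                sense = revcomp(S[h0g:w1])

                def to_g(x, c, w1=w1):
                    return (w1 - 1 - x, _COMP1[c])

            cands = v_structure_candidates(sense, len(sense), st_cfg)
            if not cands:
                return False
            truth = _v_truth_local(g, len(sense))
            key = (cands[0].region_start, cands[0].intron_len, cands[0].atg_start)
            offender = None
            if key != truth:
                offender = cands[0]
            elif len(cands) > 1 and cands[1].score(st_cfg) == cands[0].score(st_cfg):
                offender = cands[1]
            if offender is not None:
                r0, i, a0 = truth
                lp2 = st_cfg.l_part2_len
                d0 = r0 - lp2 - i
                tr_sig = {r0 - lp2 - 2, r0 - lp2 - 1, d0, d0 + 1, a0, a0 + 1, a0 + 2}
                c = offender
                sig: list[tuple[int, str]] = []
                if c.acceptor_ok:  # break only *matched* signals: that lowers the score
                    sig += [(c.region_start - lp2 - 2, "A"), (c.region_start - lp2 - 1, "G")]
                if c.donor_ok:
                    cd0 = c.region_start - lp2 - c.intron_len
                    sig += [(cd0, "G"), (cd0 + 1, "T")]
                if c.atg_ok:
                    sig += [(c.atg_start, "A"), (c.atg_start + 1, "T"), (c.atg_start + 2, "G")]
                targets.append([to_g(x, ch) for x, ch in sig if x not in tr_sig])
        for g in js:
            h = g.parts["J-HEPTAMER"]
            if g.strand == "+":
                a = g.genomic(h)[1]
                sense = S[a : a + st_cfg.max_j_region + 2]

                def to_g(x, c, a=a):
                    return (a + x, c)

            else:
                b = g.genomic(h)[0]
                a = max(0, b - st_cfg.max_j_region - 2)
                sense = revcomp(S[a:b])

                def to_g(x, c, b=b):
                    return (b - 1 - x, _COMP1[c])

            cands = j_structure_candidates(sense, st_cfg)
            truth_len = g.parts["J-REGION"][1] - g.parts["J-REGION"][0]
            if not cands:
                return False
            offender = None
            if cands[0].region_len != truth_len:
                offender = cands[0]
            elif len(cands) > 1 and cands[1].score(st_cfg) == cands[0].score(st_cfg):
                offender = cands[1]
            if offender is not None:
                L = offender.region_len
                targets.append([to_g(L, "G"), to_g(L + 1, "T")])
        if not targets:
            return True
        progressed = False
        for pairs in targets:
            for p, forbid in pairs:
                if chrom.try_mutate(p, forbid):
                    progressed = True
                    break
        if not progressed:
            return False
    return False


def simulate_locus(spec: LocusSpec, contig: str = "synthetic_tra_trd") -> LocusSim:
    """Assemble a ground-truthed chromosome carrying a TRA/TRD locus.

    Raises ``RuntimeError`` if a conflict-free chromosome cannot be produced
    (e.g. planted features would overlap under extreme parameter choices).
    """
    for attempt in range(6):
        seed = spec.rng_seed if attempt == 0 else (spec.rng_seed + 1) * 7919 + attempt
        gl = simulate_germline_set(
            LocusSpec(**{**spec.__dict__, "rng_seed": seed})
        )
        rng = np.random.default_rng(seed + 104729)
        sim = _assemble(gl, rng, spec, contig)
        if sim is not None:
            sim.spec = spec
            return sim
    raise RuntimeError("could not assemble an unambiguous locus for this spec")


def _assemble(gl: GermlineSet, rng: np.random.Generator, spec: LocusSpec,
              contig: str) -> LocusSim | None:
    vs = gl.of_type("V")
    trajs = gl.of_type("J", "TRA")
    trdjs = gl.of_type("J", "TRD")
    ds = gl.of_type("D")
    trac = next(g for g in gl.of_type("C") if g.chain == "TRA")
    trdc = next(g for g in gl.of_type("C") if g.chain == "TRD")

    locus_rank = list(rng.permutation(len(vs)))  # rank 1 first
    inv = set()
    if spec.inverted_block is not None:
        a, b = spec.inverted_block
        inv = set(range(a, b + 1))
    # chromosome is built left to right; the locus reads right to left, so the
    # V array appears in descending rank order, then TRAC, TRAJ1..n, TRDC,
    # TRDJ, and the TRDD genes with TRDD1 rightmost.
    layout: list[tuple[SimGene, str]] = []
    for i, gi in enumerate(reversed(locus_rank)):
        rank = len(vs) - i
        layout.append((vs[gi], "-" if rank in inv else "+"))
    layout.append((trac, "-"))
    for j in trajs:
        layout.append((j, "-"))
    layout.append((trdc, "-"))
    for j in trdjs:
        layout.append((j, "-"))
    for d in reversed(ds):
        layout.append((d, "-"))

    lo, hi = spec.intergenic_length_range
    pieces = [_rand_seq(rng, 700)]
    pos = 700
    for gene, strand in layout:
        gene.strand = strand
        gene.offset = pos
        block = gene.seq if strand == "+" else revcomp(gene.seq)
        pieces.append(block)
        pos += len(block)
        gap = _rand_seq(rng, int(rng.integers(lo, hi + 1)))
        pieces.append(gap)
        pos += len(gap)
    pieces.append(_rand_seq(rng, 700))
    chrom = _Chromosome("".join(pieces), rng)
    genes = [g for g, _ in layout]
    _mark_constraints(chrom, genes)
    if not _scrub(chrom, genes, RSConfig(), StructureConfig()):
        return None
    genome = str(chrom)
    for g in genes:
        g.refresh_from(genome)
    _assign_locus_names(genes)
    return LocusSim(contig=contig, genome=genome, genes=genes, spec=spec)


# ---------------------------------------------------------------------------
# Repertoire read simulation
# ---------------------------------------------------------------------------


def simulate_repertoire_reads(
    germline: GermlineSet | list[SimGene], spec: RepertoireSpec, sample: str = "sample1"
):
    """Simulate C-primed 5'-RACE amplicon read pairs.

    Returns ``(pairs, truth)`` where ``pairs`` is a list of
    ``(read_id, r1_seq, r2_seq)`` and ``truth`` a list of per-read dicts
    (true V/J names, trims, N length, productivity).  Amplicons run from the
    V leader through the junction and J into the C EX1 up to the primer
    site; read pairs always overlap so that merging can reconstruct them.
    """
    genes = germline.genes if isinstance(germline, GermlineSet) else germline
    vs = [g for g in genes if g.gene_type == "V" and g.functionality == "F"]
    js = [g for g in genes if g.gene_type == "J" and g.chain == "TRA"
          and g.functionality == "F"]
    cs = [g for g in genes if g.gene_type == "C" and g.chain == "TRA"]
    if not vs or not js or not cs:
        raise ValueError("germline set must contain >=1 functional V, J and C gene")
    c_part = cs[0].part_seq("EX1")[: spec.c_primer_offset]
    if spec.read_length < len(c_part) + 30:
        raise ValueError("read_length too short to cover the C primer region")
    rng = np.random.default_rng(spec.rng_seed)
    w = spec.usage_weights
    if w is None:
        w = np.full((len(vs), len(js)), 1.0 / (len(vs) * len(js)))
    w = np.asarray(w, dtype=float)
    if w.shape != (len(vs), len(js)):
        raise ValueError(f"usage_weights must have shape {(len(vs), len(js))}")
    if not np.isclose(w.sum(), 1.0):
        raise ValueError("usage_weights must sum to 1")

    n = spec.n_reads
    n_prod = round(spec.productive_fraction * n)
    productive = np.zeros(n, dtype=bool)
    productive[rng.permutation(n)[:n_prod]] = True
    cells = rng.choice(w.size, size=n, p=w.ravel())

    pairs, truth = [], []
    for i in range(n):
        vi, ji = divmod(int(cells[i]), len(js))
        v, j = vs[vi], js[ji]
        region = v.part_seq("V-REGION")
        jregion = j.part_seq("J-REGION")
        mode = "productive"
        if not productive[i]:
            mode = "frameshift" if rng.random() < 0.5 or spec.n_addition_max < 3 else "stop"
        for _try in range(300):
            t_v = int(rng.integers(0, spec.junction_trim_max + 1))
            t_j = int(rng.integers(0, spec.junction_trim_max + 1))
            n_ins = int(rng.integers(0, spec.n_addition_max + 1))
            v_part = v.leader_seq + region[: len(region) - t_v]
            j_part = jregion[t_j:]
            mod = (len(v_part) + n_ins + len(j_part)) % 3
            want_shift = int(rng.integers(1, 3)) if mode == "frameshift" else 0
            n_ins += (want_shift - mod) % 3
            if n_ins > spec.n_addition_max and n_ins >= 3:
                n_ins -= 3
            ins = _rand_seq(rng, n_ins)
            if mode == "stop":
                phase = (3 - len(v_part) % 3) % 3
                if n_ins < phase + 3:
                    continue  # not enough room for an in-frame stop; redraw
                ins = ins[:phase] + "TAA" + ins[phase + 3 :]
            amp = v_part + ins + j_part + c_part
            if mode == "productive" and has_stop(amp):
                continue
            if _junction_unambiguous(amp, v.leader_seq, region, t_v, jregion, t_j,
                                     len(v_part) + n_ins):
                break
        else:  # pragma: no cover
            raise RuntimeError("could not build a consistent junction")
        r1 = amp[: spec.read_length]
        r2 = revcomp(amp[-spec.read_length :])
        if spec.substitution_error_rate > 0:
            r1 = _with_errors(r1, spec.substitution_error_rate, rng)
            r2 = _with_errors(r2, spec.substitution_error_rate, rng)
        rid = f"{sample}:read{i + 1}"
        pairs.append((rid, r1, r2))
        truth.append(
            {
                "read_id": rid,
                "sample": sample,
                "v_call": v.name or f"V{vi + 1}",
                "j_call": j.name or f"J{ji + 1}",
                "productive": bool(productive[i]),
                "t_v": t_v,
                "t_j": t_j,
                "n_ins": n_ins,
                "amplicon": amp,
            }
        )
    return pairs, truth


def _junction_unambiguous(
    amp: str, leader: str, region: str, t_v: int, jregion: str, t_j: int,
    j_start: int,
) -> bool:
    """Require that V and J segment boundaries are recoverable exactly.

    Random junction nucleotides can happen to extend a germline match past
    the true trimmed boundary with a net-positive local-alignment score;
    such amplicons are rejected so that the planted V/J calls and trims
    remain the unique best-scoring interpretation of the read.
    """
    from .repertoire import _kadane  # same scoring as the assignment stage

    a = np.frombuffer(amp.encode(), dtype=np.uint8)
    for ref, d in ((region, len(leader)), (jregion, j_start - t_j)):
        r = np.frombuffer(ref.encode(), dtype=np.uint8)
        q0 = max(0, -d)
        q1 = min(len(r), len(a) - d)
        mask = a[d + q0 : d + q1] == r[q0:q1]
        _score, b, e = _kadane(mask)
        if not mask[b:e].all():
            return False
    return True


def _with_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    s = list(seq)
    for p in np.nonzero(rng.random(len(s)) < rate)[0].tolist():
        s[p] = [b for b in _BASES if b != s[p]][rng.integers(0, 3)]
    return "".join(s)


def write_fastq(pairs, r1_path: str | Path, r2_path: str | Path) -> None:
    """Write simulated pairs as FASTQ with constant qualities."""
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for rid, r1, r2 in pairs:
            f1.write(f"@{rid}/1\n{r1}\n+\n{'I' * len(r1)}\n")
            f2.write(f"@{rid}/2\n{r2}\n+\n{'I' * len(r2)}\n")
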