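"""Subgroup clustering, ortholog mapping and IMGT-style nomenclature.

V genes sharing >=75% nucleotide identity over their V-REGION belong to the
same subgroup (single-linkage: subgroup membership is any-member similarity).
Names follow the locus: TRAV<subgroup>-<rank>, the rank counted within the
subgroup along the locus 5'->3' transcriptional orientation of the
TRDD-TRDJ-TRDC-TRAJ-TRAC cluster; single-gene subgroups drop the rank
suffix.  TRAJ genes are numbered from the TRAC-proximal gene outwards, TRDD
genes from the locus 5' end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import Align

from .records import GeneAnnotation

_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 1.0
_aligner.mismatch_score = -1.0
_aligner.open_gap_score = -6.0
_aligner.extend_gap_score = -4.0


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Percent nucleotide identity over a global alignment.

    The denominator is the number of alignment columns, so gaps (including
    end gaps) count as mismatches: "ACGT" vs "ACG" gives 75.0.
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot align empty sequences")
    aln = _aligner.align(seq_a.upper(), seq_b.upper())[0]
    counts = aln.counts()
    return 100.0 * counts.identities / aln.length


@dataclass
class IdentityMatrix:
    """Symmetric percent-identity matrix over V-REGION sequences."""

    ids: list[str]
    values: np.ndarray

    @classmethod
    def from_sequences(cls, seqs: dict[str, str]) -> "IdentityMatrix":
        ids = list(seqs)
        n = len(ids)
        m = np.full((n, n), 100.0)
        for i in range(n):
            for j in range(i + 1, n):
                m[i, j] = m[j, i] = pairwise_identity(seqs[ids[i]], seqs[ids[j]])
        return cls(ids=ids, values=m)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def cluster_subgroups(matrix: IdentityMatrix, threshold: float = 75.0) -> dict[str, int]:
    """Single-linkage clustering at >= ``threshold`` percent identity.

    Returns gene id -> subgroup number; subgroups are numbered by the order
    of their first member in ``matrix.ids`` (callers pass genes in locus
    order so that subgroup 1 is the locus-5'-most).  The threshold is
    inclusive: a pair at exactly 75.0% belongs together.
    """
    n = len(matrix.ids)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if matrix.values[i, j] >= threshold:
                parent[find(i)] = find(j)
    numbering: dict[int, int] = {}
    out = {}
    for i, gid in enumerate(matrix.ids):
        root = find(i)
        if root not in numbering:
            numbering[root] = len(numbering) + 1
        out[gid] = numbering[root]
    return out


def map_orthologs(
    genes_a: dict[str, str], genes_b: dict[str, str], threshold: float = 90.0
) -> pd.DataFrame:
    """Greedy mutual-best ortholog pairing above ``threshold`` % identity.

    Pairs are accepted best-identity-first; a gene whose best counterpart is
    already taken is reported unmatched with a ``duplicate_of`` flag naming
    that counterpart.  The threshold is strict (> threshold), matching the
    "nucleotide sequence >90% similar" criterion.
    """
    pairs = []
    for na, sa in genes_a.items():
        for nb, sb in genes_b.items():
            ident = pairwise_identity(sa, sb)
            if ident > threshold:
                pairs.append((ident, na, nb))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_a: set[str] = set()
    used_b: set[str] = set()
    rows = []
    dup: dict[str, str] = {}
    for ident, na, nb in pairs:
        if na in used_a:
            continue
        if nb in used_b:
            dup.setdefault(na, nb)
            continue
        used_a.add(na)
        used_b.add(nb)
        rows.append({"gene_a": na, "gene_b": nb, "identity": ident, "status": "match"})
    for na in genes_a:
        if na not in used_a:
            rows.append(
                {
                    "gene_a": na,
                    "gene_b": dup.get(na, ""),
                    "identity": np.nan,
                    "status": "duplicate" if na in dup else "unmatched",
                }
            )
    for nb in genes_b:
        if nb not in used_b:
            rows.append({"gene_a": "", "gene_b": nb, "identity": np.nan,
                         "status": "unmatched"})
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "identity", "status"])


def assign_names(
    annotations: list[GeneAnnotation],
    subgroups: dict[int, int] | None = None,
    orientation: str = "REV",
    trac_position: int | None = None,
) -> None:
    """Assign nomenclature names in place.

    ``subgroups`` maps an annotation's index in ``annotations`` to its
    subgroup number (only needed for V genes).  ``orientation`` is the locus
    orientation on the contig ("REV": the locus 5' end is at the right).
    ``trac_position`` anchors TRAJ numbering (TRAJ1 is TRAC-proximal); when
    absent the TRAJ nearest the locus 3' end is TRAJ1, which is equivalent in
    the canonical cluster layout.
    """
    rev = orientation == "REV"

    def locus_key(a: GeneAnnotation) -> float:
        return -a.start if rev else a.start

    vs = sorted(
        (i for i, a in enumerate(annotations) if a.gene_type == "V"),
        key=lambda i: locus_key(annotations[i]),
    )
    if subgroups is not None:
        sizes: dict[int, int] = {}
        for i in vs:
            sg = subgroups.get(i)
            annotations[i].subgroup = sg
            if sg is not None:
                sizes[sg] = sizes.get(sg, 0) + 1
        rank: dict[int, int] = {}
        for i in vs:
            sg = annotations[i].subgroup
            if sg is None:
                continue
            rank[sg] = rank.get(sg, 0) + 1
            annotations[i].name = (
                f"TRAV{sg}" if sizes[sg] == 1 else f"TRAV{sg}-{rank[sg]}"
            )
    trajs = [a for a in annotations if a.gene_type == "J" and a.chain == "TRA"]
    if trac_position is None:
        trac = [a for a in annotations if a.gene_type == "C" and a.chain == "TRA"]
        trac_position = trac[0].start if trac else None
    if trac_position is not None:
        trajs.sort(key=lambda a: abs(a.start - trac_position))
    else:
        trajs.sort(key=locus_key, reverse=True)
    for i, a in enumerate(trajs):
        a.name = f"TRAJ{i + 1}"
    trdjs = sorted((a for a in annotations if a.gene_type == "J" and a.chain == "TRD"),
                   key=locus_key)
    for i, a in enumerate(trdjs):
        a.name = f"TRDJ{i + 1}"
    trdds = sorted((a for a in annotations if a.gene_type == "D"), key=locus_key)
    for i, a in enumerate(trdds):
        a.name = f"TRDD{i + 1}"
    for a in annotations:
        if a.gene_type == "C" and not a.name:
            a.name = a.chain + "C"
    names = [a.name for a in annotations if a.name]
    if len(names) != len(set(names)):
        raise RuntimeError("name collision during nomenclature assignment")


def classify_locus(annotation, threshold: float = 75.0) -> dict[str, int]:
    """Cluster the F/ORF V genes of an annotated locus and name everything.

    Returns gene name -> subgroup for the clustered V genes.  Pseudogene V
    genes get positional names in their nearest subgroup only if they cluster
    at the threshold; otherwise they stay unnamed (the paper's maps leave
    pseudogene names undisplayed).
    """
    genes = annotation.genes
    order = annotation.locus_order()
    v_idx = [genes.index(a) for a in order
             if a.gene_type == "V" and a.functionality in ("F", "ORF")]
    seqs = {
        str(i): genes[i].part_seq(annotation.genome, "V-REGION") for i in v_idx
    }
    sub_by_index: dict[int, int] = {}
    if seqs:
        matrix = IdentityMatrix.from_sequences(seqs)
        clusters = cluster_subgroups(matrix, threshold)
        sub_by_index = {int(k): v for k, v in clusters.items()}
    assign_names(genes, sub_by_index, annotation.orientation)
    return {
        genes[i].name: sg for i, sg in sub_by_index.items() if genes[i].name
    }
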