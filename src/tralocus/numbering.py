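"""IMGT-style unique numbering of TR V domains.

The IMGT unique numbering assigns fixed positions to the V-domain framework:
FR1 spans positions 1-26 (1st-CYS at 23), CDR1 occupies the 27-38 window,
FR2 spans 39-55 (conserved Trp at 41), CDR2 the 56-65 window, FR3 spans
66-104 (hydrophobic 89, 2nd-CYS at 104); residues beyond 104 belong to the
(germline) CDR3.  Shorter CDRs leave gaps in the middle of their window.

Numbering is computed against a packaged synthetic scaffold (an invented,
TR-alpha-like full-occupancy template) by exhaustively choosing the CDR1 and
CDR2 lengths that maximise framework similarity — a deterministic restriction
of template alignment that is exact whenever the framework regions carry no
insertions or deletions.  Sequences whose frameworks do not reach a minimal
similarity to the scaffold raise :class:`NumberingError`.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Align import substitution_matrices

FR1_LEN, CDR1_MAX, FR2_LEN, CDR2_MAX, FR3_LEN = 26, 12, 17, 10, 39

#: synthetic numbering scaffold (full CDR occupancy; 104 positions)
TEMPLATE_FR1 = "GQSVTQPEKLLSVSEGDSATLNCTYS"
TEMPLATE_CDR1 = "DSASNYGSYYLT"
TEMPLATE_FR2 = "PAWYRQFPGEGPALLIS"
TEMPLATE_CDR2 = "IRSNEREKHS"
TEMPLATE_FR3 = "GRFTAQLNKASKYFSLLIRDSQPLSDSATYFSAKGEVSC"
TEMPLATE = TEMPLATE_FR1 + TEMPLATE_CDR1 + TEMPLATE_FR2 + TEMPLATE_CDR2 + TEMPLATE_FR3

assert len(TEMPLATE_FR1) == FR1_LEN and TEMPLATE_FR1[22] == "C"
assert len(TEMPLATE_CDR1) == CDR1_MAX
assert len(TEMPLATE_FR2) == FR2_LEN and TEMPLATE_FR2[2] == "W"
assert len(TEMPLATE_CDR2) == CDR2_MAX
assert len(TEMPLATE_FR3) == FR3_LEN and TEMPLATE_FR3[23] == "L" and TEMPLATE_FR3[38] == "C"
assert len(TEMPLATE) == 104

_BLOSUM = substitution_matrices.load("BLOSUM62")


class NumberingError(ValueError):
    """Raised when a sequence cannot be assigned IMGT positions."""


@dataclass(frozen=True)
class NumberedVDomain:
    """A V domain with IMGT positions assigned.

    ``gapped`` is the 104-column framework/CDR1/CDR2 string ('.' for missing
    positions) with the germline CDR3 appended; the ``cdr_lengths`` triplet
    is (CDR1, CDR2, germline CDR3), printed in census tables as e.g. [7.6.3].
    """

    gapped: str
    residue_23: str
    residue_41: str
    residue_89: str
    residue_104: str
    cdr_lengths: tuple[int, int, int]
    fr_lengths: tuple[int, int, int]

    @property
    def has_conserved_triad(self) -> bool:
        return self.residue_23 == "C" and self.residue_41 == "W" and self.residue_104 == "C"

    @property
    def triplet(self) -> str:
        c1, c2, c3 = self.cdr_lengths
        return f"[{c1}.{c2}.{c3}]"


def _block_score(a: str, b: str) -> float:
    s = 0.0
    for x, y in zip(a, b):
        try:
            s += _BLOSUM[x, y]
        except (KeyError, IndexError):
            s -= 4.0
    return s


def _pad_cdr(cdr: str, width: int) -> str:
    """Place a short CDR in its window, gaps in the middle (IMGT rule)."""
    left = (len(cdr) + 1) // 2
    return cdr[:left] + "." * (width - len(cdr)) + cdr[left:]


def imgt_number_v(
    v_aa: str, template: str = TEMPLATE, min_fr_identity: float = 0.30
) -> NumberedVDomain:
    """Assign IMGT unique-numbering positions to a V-domain amino-acid string.

    ``v_aa`` must be the stop-free translation of a V-REGION (framework 1
    through the germline CDR3).  The CDR1/CDR2 lengths maximising framework
    similarity to the template are selected; ties prefer shorter CDRs.
    """
    if "*" in v_aa:
        raise NumberingError("cannot number a translation containing stop codons")
    if template != TEMPLATE and len(template.replace(".", "")) != 104:
        raise NumberingError("numbering template must provide 104 positions")
    tfr1 = template[:FR1_LEN]
    tfr2 = template[FR1_LEN + CDR1_MAX : FR1_LEN + CDR1_MAX + FR2_LEN]
    tfr3 = template[-FR3_LEN:]
    min_len = FR1_LEN + FR2_LEN + FR3_LEN
    if len(v_aa) < min_len:
        raise NumberingError(f"sequence too short to number ({len(v_aa)} aa)")
    best = None
    cdr3_budget = len(v_aa) - min_len
    for c1 in range(0, min(CDR1_MAX, cdr3_budget) + 1):
        for c2 in range(0, min(CDR2_MAX, cdr3_budget - c1) + 1):
            p = 0
            fr1 = v_aa[p : p + FR1_LEN]
            p += FR1_LEN + c1
            cdr1 = v_aa[p - c1 : p]
            fr2 = v_aa[p : p + FR2_LEN]
            p += FR2_LEN + c2
            cdr2 = v_aa[p - c2 : p]
            fr3 = v_aa[p : p + FR3_LEN]
            p += FR3_LEN
            score = _block_score(fr1, tfr1) + _block_score(fr2, tfr2) + _block_score(fr3, tfr3)
            key = (score, -c1, -c2)
            if best is None or key > best[0]:
                best = (key, c1, c2, fr1, cdr1, fr2, cdr2, fr3, v_aa[p:])
    assert best is not None
    _, c1, c2, fr1, cdr1, fr2, cdr2, fr3, cdr3 = best
    frs = fr1 + fr2 + fr3
    ident = sum(a == b for a, b in zip(frs, tfr1 + tfr2 + tfr3)) / len(frs)
    if ident < min_fr_identity:
        raise NumberingError(
            f"framework identity to numbering template too low ({ident:.2f})"
        )
    gapped = (
        fr1 + _pad_cdr(cdr1, CDR1_MAX) + fr2 + _pad_cdr(cdr2, CDR2_MAX) + fr3 + cdr3
    )
    return NumberedVDomain(
        gapped=gapped,
        residue_23=fr1[22],
        residue_41=fr2[2],
        residue_89=fr3[23],
        residue_104=fr3[38],
        cdr_lengths=(c1, c2, len(cdr3)),
        fr_lengths=(FR1_LEN, FR2_LEN, FR3_LEN),
    )


def align_v_domains(seqs: dict[str, str]) -> dict[str, str]:
    """IMGT-anchored multiple alignment of V-domain amino-acid sequences.

    Every sequence is numbered against the scaffold; the gapped strings share
    the 104 framework/CDR columns, and CDR3 tails are right-padded to the
    longest.  This anchored alignment stands in for a progressive aligner for
    template-compatible sequences (e.g. the synthetic loci).
    """
    numbered = {name: imgt_number_v(aa) for name, aa in seqs.items()}
    width = max(len(n.gapped) for n in numbered.values())
    return {name: n.gapped.ljust(width, ".") for name, n in numbered.items()}
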