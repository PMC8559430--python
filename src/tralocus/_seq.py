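"""Small sequence helpers shared across modules."""

from __future__ import annotations

_COMP = str.maketrans("ACGTRYKMBVDHacgtrykmbvdh", "TGCAYRMKVBHDtgcayrmkvbhd")

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

# Codons per amino acid, for random back-translation.
AA_CODONS: dict[str, list[str]] = {}
for _codon, _aa in CODON_TABLE.items():
    AA_CODONS.setdefault(_aa, []).append(_codon)
for _aa in AA_CODONS:
    AA_CODONS[_aa].sort()


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(_COMP)[::-1]


def translate(seq: str) -> str:
    """Translate frame 0; trailing partial codon is ignored; stops are '*'."""
    n = len(seq) - len(seq) % 3
    return "".join(CODON_TABLE.get(seq[i : i + 3], "X") for i in range(0, n, 3))


def has_stop(seq: str) -> bool:
    """True if frame-0 translation of ``seq`` contains a stop codon."""
    n = len(seq) - len(seq) % 3
    return any(seq[i : i + 3] in STOP_CODONS for i in range(0, n, 3))
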