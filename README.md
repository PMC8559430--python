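# tralocus

Annotation of teleost TRA/TRD loci and TR-alpha repertoire profiling.

In salmonids (Atlantic salmon, rainbow trout) the T-cell receptor alpha/delta
locus carries hundreds of V gene segments downstream of a
TRDD–TRDJ–TRDC–TRAJ–TRAC cluster, the cluster inverted relative to the V
array. Curating such a locus means finding every V, D, J and C gene from raw
genomic sequence, deciding which are functional, grouping the V genes into
subgroups and naming them consistently — and only then can high-throughput
TR-alpha repertoire sequencing be interpreted against the germline.
`tralocus` implements that workflow end to end for people building or
consuming salmonid-style TR locus annotations:

* **Germline discovery.** Constant genes are localised from cDNA queries and
  define the locus orientation. Recombination signal (RS) motifs — heptamer
  `CACAGTG` / nonamer `ACAAAAACC` with 12- or 23-bp spacers — are scanned
  genome-wide with configurable mismatch tolerances, and each hit is tested
  against the structural grammar of a TR gene: V genes need an ATG leader
  (L-PART1), a GT..AG intron, an L-PART2 and a V-REGION ending at a 23-spacer
  RS; J genes run from a 12-spacer RS through an FGXG-bearing J-REGION to a
  GT donor; D genes sit between a 12/23 RS pair.
* **Functionality (IMGT-style).** F: open reading frame, intact splice
  sites and RS, conserved 1st-CYS 23 / Trp 41 / 2nd-CYS 104 under the IMGT
  unique numbering; ORF: intact reading frame but splice/RS/motif defects;
  P: stop codons or frameshifts.
* **Subgroups and nomenclature.** V genes cluster at ≥75% V-REGION
  nucleotide identity (single linkage); names are `TRAV<subgroup>-<rank>`
  with the rank counted along the locus 5'→3', TRAJ1 adjacent to TRAC,
  TRDD1 at the locus 5' end. Orthologs across assemblies are paired at
  >90% identity.
* **Phylogenetics.** Poisson-corrected amino-acid distances
  (d = −ln(1 − p), pairwise deletion), neighbor-joining trees and
  column-resampling bootstrap supports.
* **Repertoire pipeline.** FLASH-style read-pair merging (extended reads
  >150 bp), BLAST-style assignment of C/J/V segments against the germline
  (97% identity hit floor; assignment requires a C hit >30 bp, J and V hits
  >99.9% identity, V over ≥50 bp; duplicates removed by expectancy),
  six-frame productivity calling through the V–J junction, median-of-ratios
  log2 normalisation, and V×J usage tables and heatmaps.
* **Synthetic data.** A first-class generator plants ground-truthed loci
  (controlled subgroup identities, pseudogene/ORF fractions, inverted V
  blocks) and C-primed 5'-RACE amplicon read pairs (junction trimming,
  N-addition, exact productive fractions, substitution errors), so every
  stage is testable without downloads.

## Worked example

```python
from tralocus.simulate import LocusSpec, simulate_locus
from tralocus.annotate import annotate_locus
from tralocus.subgroups import classify_locus

sim = simulate_locus(LocusSpec(n_subgroups=4, genes_per_subgroup=(2, 3), rng_seed=1))
ann = annotate_locus(sim.genome, sim.c_queries(), contig=sim.contig)
classify_locus(ann)

print(f"contig length: {len(ann.genome):,} bp, orientation {ann.orientation}")
for g in ann.locus_order():
    if g.gene_type == "V" and g.functionality in ("F", "ORF"):
        print(f"  {g.name:<10} {g.start:>6}-{g.end:<6} {g.strand} "
              f"{g.functionality:<3} CDR {g.notes.get('cdr_triplet')}")
```

prints

```
contig length: 15,145 bp, orientation REV
  TRAV1-1      7413-7914   + F   CDR [9.6.3]
  TRAV2-1      6643-7112   + F   CDR [4.1.3]
  TRAV3-1      5971-6453   + F   CDR [7.2.3]
  TRAV2-2      3755-4225   + F   CDR [4.1.3]
  TRAV1-2      3042-3539   + F   CDR [9.6.3]
  TRAV2-3      2406-2867   + F   CDR [4.1.3]
  TRAV4        1532-2007   + ORF CDR [7.2.3]
  TRAV3-2       700-1176   + F   CDR [7.2.3]
```

`orientation REV` means the C genes transcribe right-to-left on the contig,
so the locus 5' end (the TRDD genes) is at the right and V ranks count from
the cluster-proximal end; the bracketed triplet is the IMGT CDR1/CDR2/
germline-CDR3 length of each V domain (the single-member subgroup TRAV4
carries no rank suffix). The full run also reports 8 F + 1 ORF + 2 P TRAJ
genes, one FGKA-motif TRDJ, three TRDD genes (8/13/14 nt) and the two
three-exon constant genes.

The same stages are available from the shell:

```
tralocus all --out run/ --seed 1          # simulate → annotate → classify
                                          #   → phylo → repertoire → report
tralocus annotate --genome chr.fa --c-queries C.fa --out run/
tralocus repertoire --r1 A_1.fq --r2 A_2.fq --germline germline.fa --out run/
```

Each run directory contains a GFF3 annotation, per-class FASTA, a subgroup
census TSV, a Newick tree with bootstrap supports, an AIRR-style
rearrangement table, usage matrices and figures, plus a `manifest.json`
recording the configuration hash and input checksums.

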