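# Methods

## The locus model

`tralocus` treats a TRA/TRD locus as a sequence of structured gene cassettes
on a single contig. Reading the forward strand of the canonical teleost
arrangement, the V array comes first and the TRAC–TRAJ–TRDC–TRDJ–TRDD
cluster follows in inverted orientation; the locus orientation is defined by
the transcriptional direction of the constant genes, so on such a contig the
locus reads 5'→3' from the TRDD end and the V genes point *towards* the
cluster (rearrangement by inversion). All coordinates are 0-based
half-open internally and 1-based inclusive in GFF3. A gene's annotated span
covers its RS plus coding region(s); C genes span their three exons.

The structural grammar (module `genemodel`) is shared by the generator and
the annotator:

* **RS motif.** Heptamer `CACAGTG`, nonamer `ACAAAAACC`. Detection accepts
  ≤1 heptamer mismatch with the `CAC` core exact and ≤3 nonamer mismatches;
  spacers 22–23 bp for V and 3'D-RS, 11–13 bp for J and 5'D-RS. An RS is
  *functional* (compatible with rearrangement) at 0 heptamer and ≤1 nonamer
  mismatches. The detection/functionality split keeps genes with an RS
  defect discoverable while still demoting them to ORF. All thresholds are
  configurable (`RSConfig`); the defaults follow the canonical 12/23
  architecture and the 22-bp V-spacer expectation.
* **V structure.** ATG-initiated L-PART1 (37 nt), GT..AG intron (annotator
  search range 80–120 nt), 11-nt L-PART2, V-REGION of 200–360 nt ending at
  the heptamer. Candidates must present at least two of the three
  delimiting signals (acceptor AG, donor GT, leader ATG), so a single
  planted splice defect remains delimitable; candidates are ranked by
  (signal count, leader stop-free, intron length closest to 100, region
  length closest to 294) — the preference anchors are pure tie-breakers.
* **J structure.** J-REGION from the heptamer to a GT donor, 30–80 nt;
  candidates are ranked by (FGXG motif present, length divisible by three,
  length closest to 51). The motif and frame are scored rather than
  required so ORF and pseudogene J genes are still delimited.
* **D structure.** A 4–40 nt D-REGION between a 12-spacer and a 23-spacer
  RS on consistent strands; stop codons in any frame are flagged but do not
  block emission.
* **C genes** are localised from spliced cDNA queries by edlib seeding and
  a greedy exon walk across GT..AG introns (intron range 70–130 nt,
  mismatch budget 8, identity floor 90%).

### Functionality

Deterministic mapping, applied after structural delimitation: stop codon or
frameshift → P; splice or RS defect → ORF; missing FGXG in a TRAJ → ORF
(the single salmonid TRDJ carries an FGKA variant motif and is exempt);
everything else → F. A substitution of a conserved residue (1st-CYS 23,
Trp 41, 2nd-CYS 104) is always *recorded* but demotes F→ORF only under
`strict_conserved`: functional genes with a substituted 1st-CYS exist in
real salmonid loci, so the demotion cannot be made mechanical.

### IMGT numbering

V domains are numbered against a packaged synthetic scaffold (an invented,
TR-alpha-like 104-position template; it is *not* a natural sequence). The
CDR1/CDR2 lengths that maximise BLOSUM62 framework similarity are chosen by
exhaustive search over the 13 × 11 possibilities — a deterministic
restriction of template alignment that is exact whenever the frameworks
carry no indels. Framework identity below 30% raises a numbering error.
Sequences with framework indels (which occur in real V genes) are numbered
only approximately; this is a known limitation. The same numbering anchors
the multiple alignment used for phylogenetics (`align_v_domains`), which
stands in for a progressive aligner for template-compatible sequences.

## Subgroups, orthologs, names

Percent identity is computed over a global alignment (match +1, mismatch
−1, gap −6/−4 linear-ish) with *alignment columns* as the denominator, so
end gaps count as mismatches; the stiff gap penalties make substitution-only
alignments optimal at the divergences of interest, hence "75 substitutions
in 300 nt" is exactly 75.0%. Subgroups are single-linkage connected
components at ≥75% (inclusive) — subgroup membership in practice is
any-member similarity. Orthologs across assemblies pair greedily,
best-identity-first, strictly above 90%; a gene whose best counterpart is
taken is flagged as a duplicate. Names follow the locus: subgroup numbers
by order of first F/ORF member along the locus 5'→3', ranks within
subgroup along the locus, no rank suffix for single-member subgroups,
TRAJ1 TRAC-proximal, TRDD1 at the locus 5' end. Pseudogene V genes are not
clustered and receive placeholder names.

## Phylogenetics

Poisson distance d = −ln(1 − p) with pairwise deletion of gapped columns;
p ≥ 1 raises an explicit error rather than returning infinity silently.
Neighbor joining uses the classical Q criterion with ties broken by taxon
order (deterministic), is exact on additive matrices, and clamps negative
branch lengths to zero with a warning. Bootstrap supports are the
percentage of 500 (default) column-resampled NJ replicates containing each
bipartition; bipartitions are canonicalised (smaller side of each internal
edge) so splits compare across differently rooted trees. Maximum-likelihood
tree search is out of scope; the NJ implementation is cross-checked against
an independent library implementation in the test suite.

## Repertoire pipeline

* **Merging.** Per pair, the overlap (≥10 nt) with the lowest mismatch
  density (≤0.25) wins, largest overlap on ties; disagreements resolve to
  the mate whose copy lies farther from its sequencing 3' end. Extended
  reads must exceed 150 bp.
* **Assignment.** Substitution-only (gapless) seed-and-extend local
  alignment: shared 15-mers define diagonals, and per diagonal the optimal
  segment under match +1 / mismatch −2 is taken (Kadane), ties resolving to
  the shortest (highest-identity) segment. Any hit reported must reach 97%
  identity over ≥30 bases, and at those thresholds every qualifying
  segment necessarily contains an exact 15-mer, so seeding is lossless and
  the aligner agrees exactly with brute-force enumeration (tested). The
  expectancy is a Karlin–Altschul-style E-value on the (+1/−2) scores; only
  its monotonicity matters, since it orders duplicate hits.
* **Filters** (applied per read after keeping the best hit per class by
  expectancy, ties to higher identity then name): C hit length strictly
  greater than 30; J identity strictly greater than 99.9%; V identity
  strictly greater than 99.9% over ≥50 bases. For references shorter than
  1000 nt the strict 99.9% cut effectively demands a perfect aligned span.
  Every dropped read carries its first failing criterion.
* **Productivity.** A read is productive iff V and J share a strand, the
  distance from the V-REGION frame anchor to the J-REGION 3' end is a
  multiple of three, and the translation from the anchor through the
  junction and J into the first 15 nt of the constant region is stop-free.
  This anchored check is equivalent to scanning all six reading frames for
  a frame concordant with both germline segments.
* **Normalisation.** Size factors are median-of-ratios against a
  geometric-mean pseudo-reference with zeros excluded, computed on
  *library-scale-decoupled* profiles: each sample's geometric mean of
  nonzero counts is factored out before the reference is built and
  multiplied back into the factor. This keeps the familiar median-of-ratios
  behaviour while making each sample's normalised values `log2(c/sf + 1)`
  exactly invariant to rescaling that sample's library — doubling a
  sample's counts doubles its size factor and changes nothing else. The
  textbook single-pass median-of-ratios does not have this invariance (the
  pseudo-reference itself shifts by 2^(1/n)), which is why the two-pass
  form was adopted. It remains a documented stand-in for a regularised log
  transform, not a reimplementation of one; variance shrinkage is out of
  scope.
* **Usage.** Per-sample V×J count matrices and marginals, separately for
  productive and unproductive reads; frequencies as percentages of the
  sample's reads within each productivity class (they sum to 100);
  per-V conditional J-usage rows summing to 100; J usage against genomic
  position. Figures are pure views: every plotted matrix is written as a
  TSV first.

## The synthetic-data generator

The generator emits loci whose statistical structure matches what the
annotator assumes, with exact ground truth.

* **V genes.** Each subgroup draws CDR lengths (CDR1 4–9, CDR2 0–10,
  germline CDR3 3) and builds an ancestor V-REGION from shared framework
  codon roots; members mutate at rate (1 − within-identity)/2 and subgroup
  ancestors at (1 − between-identity)/2, never touching the conserved
  codons, never creating stops, so pairwise identities land near the
  requested targets (defaults 0.86 within / 0.55 between, straddling the
  75% threshold as the recoverability invariant requires).
* **Defects.** Pseudogene and ORF fractions are exact rounded counts.
  P genes get a stop codon or a single-nucleotide frameshift; ORF genes a
  detectable-but-nonfunctional RS (1 heptamer mismatch outside the core, or
  2 nonamer mismatches) or a mutated splice donor. Splice defects are
  planted on the donor only: a broken acceptor leaves the V-REGION 5' limit
  structurally unpinned (every region length then shares the surviving
  donor+ATG signals), so acceptor defects cannot be recovered with exact
  coordinates by any annotator using this grammar. ORF J genes lose their
  FGXG; the TRDJ encodes the conserved FGKA variant and stays functional.
* **Layout.** V genes (locus ranks permuted) on the forward strand, the
  cluster inverted, intergenic spacers 150–400 bp, optional inverted V
  block; TRDD lengths 8/13/14 nt with all three frames open; C genes have
  three exons (120/150/63 nt) encoding a 110-aa constant domain.
* **Ambiguity scrubbing.** Exact-recovery guarantees are only well-posed if
  the planted structure is the *unique* best-scoring interpretation. After
  assembly the chromosome is scrubbed: spurious RS-motif matches and any
  structural candidate that ties or outranks a planted gene under the
  annotator's deterministic scoring are destroyed by point mutations in
  unconstrained positions (intergenic bases, spacers, intron interiors, or
  coding positions where no stop/motif constraint is violated). The loop is
  deterministic under the seed and typically converges in a few rounds; a
  locus that cannot be disambiguated is rebuilt from a derived seed. This
  is the structural analogue of the identity-separation invariant — a
  ground-truth well-posedness contract, not a statement about real genomes,
  where manual curation faces exactly these ambiguities.
* **Reads.** Amplicons run leader → trimmed V-REGION → N nucleotides →
  trimmed J → the first 60 nt of C EX1 (the primer site), ≈420–480 bp, so
  250-nt read pairs always overlap. Trims and N lengths are uniform on
  [0, 6] by default; the productive fraction is exact by construction
  (frame forced or broken at the junction; unproductive reads are half
  frameshifts, half in-frame stops). Junctions are rejection-sampled so
  that the maximal-scoring V and J segments end exactly at the planted
  boundaries — random junction bases can otherwise extend a germline match
  net-positively and push the hit below the strict identity filter, which
  is a real ambiguity of real junctions that the ground-truth contract
  must exclude. Sequencing noise is substitution-only; qualities are
  constant because the pipeline never reads them.

What passing tests on this generator do *not* show: performance on real
assemblies with assembly gaps, repeat-induced false RS hits, framework
indels, allelic variation, or junction ambiguity — the generator
deliberately excludes all of these so that recovery can be asserted
exactly.

## Problem sizes and defaults

Default synthetic loci carry 8 subgroups × 3–7 V genes plus 10 TRAJ, one
TRDJ, three TRDD and two C genes (≈50–60 genes, ≈35–45 kb). The recovery
battery uses 20 seeded loci; the repertoire battery uses 10,000 error-free
read pairs plus a 10,000-read 4 V × 5 J uniform design for the
frequency-recovery check (every cell within 3 multinomial SD); bootstrap
checks use 500 replicates. These sizes exercise every code path while
keeping the full suite inside a few minutes on one CPU.

## Known limitations

* The numbering scheme assumes indel-free frameworks (see above).
* The C-gene finder assumes high query identity (≥90%) and canonical
  GT..AG introns; degenerate splice sites are reported as defects, not
  modelled.
* The expectancy is not a calibrated BLAST E-value; only its ordering is
  used.
* `pair_d_hits` pairs each RS hit at most once, smallest D first; nested
  or overlapping D cassettes would need manual review.
* The normalisation is a stand-in transform (see above), not a variance-
  stabilising rlog.
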