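# Methods

`mobilome` compares two near-identical assemblies of one bacterial
strain lineage — here called the *wildtype* (genome A) and the *mutant*
(genome B) — and attributes their differences to mobile genetic
elements. This note records the models, conventions and numerical
choices behind each stage, what the synthetic fixture does and does not
emulate, and the known limitations.

## Coordinate conventions

All in-memory intervals are 0-based, half-open; every on-disk emission
(GFF3, TSV reports) is 1-based, inclusive. An element occurrence
interval **excludes** its target-site duplication (TSD): the TSD is
host sequence duplicated on insertion, so the element proper is the
sequence between the two copies. A consequence worth knowing: the
sequence difference between a carrier and a non-carrier strain at an
insertion locus is *element + one TSD copy*, so an insertion call (and
a PCR product difference across the locus) is longer than the element
by one TSD length. For the 187-nt MITE with an 8-nt TSD the called
insertion is 195 nt and an amplicon pair across the locus differs by
195 bp, not 187.

Translation uses the bacterial code (table 11); GTG/TTG starts are
translated as written — initiator handling belongs to the caller.
Ambiguity codes other than N are rejected at parse time so that exact
string matching downstream stays well-defined. Genomes are treated as
linear; wrap-around matches on a rotated circular chromosome are not
searched.

## IS-element cataloguing

Known elements are located by seed-and-extend: exact 13-mer seeds
against the genome, candidate loci clustered by implied start, then a
banded semi-global alignment (edlib, mismatch budget from the identity
threshold) to score each candidate. Identity is `1 - editDistance /
|element|`; coverage is hit span over element length. Defaults
`min_identity = 0.90`, `min_coverage = 0.5` play the role a BLASTn
e-value cutoff plays in database searches, expressed as explicit,
deterministic thresholds rather than an e-value emulation.

Overlapping hits are de-duplicated by a greedy pass over a total order
(longer span, then higher identity, then leftmost): whenever two hits
overlap by at least half of the shorter one's span, the shorter is
removed. The greedy pass over a total order equals iterated all-pairs
removal, so the operation is idempotent.

Copy counting has two modes. *Exact* counts distinct non-overlapping
occurrences of the element or its reverse complement, leftmost-greedy,
with palindromes counted once — appropriate for young, identical
element families. *Approximate* counts deduped seed-and-extend hits at
the configured identity, for diverged cross-strain homologs.

## MITE discovery

A miniature inverted-repeat transposable element is short (< ~500 bp),
present in many identical copies, carries terminal inverted repeats
(TIRs) and TSDs, encodes no transposase, and folds into a hairpin.
Discovery applies those criteria in order:

1. **High-copy repeat mining.** Exact 21-mer seeds with at least
   `min_copies` (default 5) occurrences over both strands are extended
   outward while *every* occurrence stays identical; the element
   boundary emerges naturally because each copy's flanks (including
   its private TSD) differ. Seeds are processed in descending
   occurrence order: a k-mer straddling a copy's TSD junction is shared
   only by the subset of copies whose TSDs happen to end alike, and
   extending such a fragment first would shadow the element's own
   seeds. Candidates contained in (or containing) a higher-copy
   candidate are suppressed as junction fragments. Exact mining is the
   right model for a young family of identical copies; relaxed-identity
   homolog search across strains goes through the catalog matcher
   instead.
2. **TSD call.** The largest `w` in [2, 16] with identical flanks
   immediately left and right of the occurrence. Insufficient flank at
   a contig end raises an error, deliberately distinct from "absent".
3. **TIR call.** The longest ungapped alignment of the 5' prefix
   against the reverse complement of the 3' suffix with at most 2
   substitutions, with the refinement that the innermost aligned
   position must be a match. Without that trimming rule, the "longest
   with ≤ k mismatches" criterion almost always overshoots the
   biological TIR boundary by k terminal mismatches that carry no
   repeat evidence.
4. **ORF scan.** ATG-only starts, all six frames, stop codon included
   in the span, one (longest) ORF per stop, minimum span 30 nt.
   Reported 1-based within the element, start > end on the minus
   strand — the convention of the common ORF finders. ORFs that run
   off the element without a stop are not reported.
5. **Fold score.** Nussinov base-pair maximization with Watson–Crick
   plus GU pairs and minimum loop length 3, reported as pair count and
   pairing fraction (2·pairs/length). This is a deliberate stand-in for
   thermodynamic folding: a hairpin-forming MITE shows a high pairing
   fraction without an energy model, and the quantity is exactly
   testable against brute-force enumeration.
6. **Verdict.** MITE iff TIR present ∧ at least one TSD-positive locus
   ∧ no ORF ≥ 600 nt (a conservative lower bound for a transposase
   coding region) ∧ copy number ≥ the mining threshold. Otherwise the
   first failed criterion is the rejection reason.
7. **Family linkage.** A transposase family is a candidate mobilizer
   when one of its catalog hits carries termini matching the MITE's
   terminal 9-mers (≤ 1 mismatch per end, element orientation) *and*
   that hit's own TSD length equals the MITE's modal TSD length. The
   TSD-length clause matters: it is the family fingerprint that
   excludes decoy families sharing the seed by chance. Multiple
   qualifying families are all reported, flagged ambiguous.

## Structural comparison of the two assemblies

Whole-genome alignment is replaced by unique-k-mer anchoring: 21-mers
whose combined forward+reverse-complement count is exactly one in both
genomes are matched (orientation-aware) and merged into maximal
co-diagonal runs. Runs bridge non-unique stretches (shared repeats) on
the same diagonal only when the intervening sequence is verified
identical, so anchors of two identical genomes collapse to a single
full-length anchor, and every anchor string is guaranteed identical
between the genomes. In a ~99.9%-identical pair, unique anchors tile
everything except repeats — which is precisely where the interesting
differences live.

**Inversions** are maximal runs of inverted-orientation anchors of at
least 10 kb, with breakpoints at the outermost anchored base. The
flanking repeat is the maximal sequence identical between the two
breakpoint flanks of one genome, found in linear time with a KMP
prefix function (a per-length scan would be quadratic in the ~10-kb
cassettes involved); its genome-wide copy number is counted by exact
occurrence counting, which is the planted regime — a diverged-copy
count at 99% identity is available through the approximate counter but
is not the default path.

**Insertions** are gaps between adjacent same-orientation anchors that
are ≥ 50 nt in exactly one genome and ≤ 10 nt in the other. Anchor
overlap caused by a TSD is trimmed leftward, so calls are
left-normalized: an insertion whose last bases equal the preceding
host bases is reported at its leftmost equivalent placement. Gap pairs
that fail the 10-nt asymmetry tolerance are reported as *complex
regions* rather than forced into either class; gaps with identical
content (unanchored shared repeats) are not differences and are
dropped. Inserted sequences are attributed to catalog elements by
exact containment, falling back to a 90%-identity edlib check.

**Intra-genome duplications** are found by pairing k-mers with 2–6
forward occurrences, grouping pairs by diagonal, merging runs (gaps up
to 5 kb bridge nested higher-copy repeats inside the duplication), and
verifying the merged intervals by direct comparison — exact runs score
identity 1.0, otherwise an edit-distance identity with a 0.99 floor.
Only direct (same-orientation) duplications are searched.

## Genic impact

An insertion is classified against the annotation of the genome that
does *not* carry it, where the site is a single position: intragenic
iff strictly inside a CDS; a site at an exact CDS boundary is
intergenic at distance 0. For an interrupted CDS, product 1 is the
translation from the original start to the first in-frame stop at or
after the junction; product 2 is the longest ATG-initiated ORF (≥ 30
nt, forward frames only — the transcript is single-stranded) in the
remainder of the interrupted transcript. The CDS length change from a
stop-ablating insertion is computed by re-running the frame through
the mutated sequence to its first stop. Note that both the old and new
coding regions are codon multiples, so this delta is always a multiple
of 3; annotation-derived "extension" figures that are not multiples of
3 cannot be reproduced by frame arithmetic and should be read as
genomic end-shifts.

## Expression overlay

Input is a long-format TPM table (gene × strain × timepoint ×
replicate). Contrasts are per gene and timepoint: a Welch
unequal-variance t-test on TPM values (chosen over the pooled test
because duplicate/triplicate TPMs are routinely heteroscedastic), BH
adjustment within each timepoint, and a fold-change filter on
pseudocounted means (+1 TPM, guarding division by zero). Significance
is inclusive on both thresholds (fold ≥ 2, q ≤ 0.05). Groups that tie
exactly get p = 1 at equal means, or a relative variance floor
(1e-8 × mean²) at unequal means, rather than being dropped — ties are
common in low-count TPM data.

**Statistical power.** With two replicates per group, the Welch
statistic has Satterthwaite df between 1 and 2, so the two-sided p
cannot fall much below t⁻²; under a BH family of hundreds to thousands
of genes, q ≤ 0.05 then requires p-values a two-replicate test cannot
reliably produce, even at 4-fold effects with 10% CV. Measured on the
generator's own tables, the median recall of planted ≥4-fold effects
at q ≤ 0.05 is ~0.2 with n = 2, and ≥ 0.95 with n = 5. The generator's
default is five replicates per strain × timepoint (forty libraries
over two strains and four timepoints); screens designed with duplicate
libraries should expect to miss most true 4-fold effects at FDR 0.05,
and the acceptance report prints the recall at both depths rather than
hiding the n = 2 result.

The overlay joins each insertion to the genes it can plausibly
regulate: the interrupted gene for intragenic insertions (always
included), otherwise up to 4 genes within 5 kb that read away from the
site on their own strand, plus both immediate neighbors — one row per
(insertion, gene, timepoint) with the DE flags attached.

## In-silico PCR

Primer sites are scanned on both strands with an optional mismatch
budget and a 3'-terminal region (default 3 nt) that must match exactly
— extension requires an annealed 3' end. Product length runs from the
forward primer's 5' base through the reverse primer's 5' base
inclusive (the size a gel reports). Both primer orientations are
searched, so swapping forward and reverse primers yields the same
products.

## The synthetic fixture

The generator emits a backbone (i.i.d. bases at 42% GC — typical for
the cyanobacterial genomes this pipeline targets; i.i.d. rather than
Markov because repeat discovery depends only on planted repeats and
i.i.d. makes false-positive rates analyzable), non-overlapping genes of
300–3,000 nt written as clean CDSs, and a planted inventory whose
default ("pcc7806-mimic", 1 Mb) mirrors the mobile-element inventory of
a *Microcystis aeruginosa* PCC 7806 wildtype / toxin-gene-knockout
strain pair, scaled into one megabase so the suite runs in seconds:

- a 187-nt MITE with the terminal seed `GGCTCTTCG`, one internal
  substitution in the 3' TIR (imperfect, as real MITE TIRs are),
  designed extension blockers so the TIR is exactly 9 nt, 8-nt TSDs,
  and 31 shared + 2 mutant-specific copies (33/31). One mutant copy
  interrupts a designed 1,044-nt sulfate-binding-protein gene at codon
  286; validation primers around that locus give a 189-bp wildtype and
  384-bp mutant product;
- a 1,215-nt ISL3-like transposase sharing the MITE's termini and TSD
  length (2 copies each strain) — the planted mobilizer;
- a 1,746-nt IS1634-like element (10/8), one mutant copy inserted
  upstream of a 3-gene operon whose members carry 0.25× expression in
  the mutant;
- a 444-nt IS200-like element without TIRs or TSDs (14/16), one
  wildtype-specific copy intragenic;
- a 737-nt IS1-like element (5/6), the wildtype-specific copy sitting
  before a 2-gene cluster silenced (0.1×) in the wildtype;
- a 200-kb inversion whose breakpoints are flanked by a 10-kb cassette
  present in 3 copies per genome; cassette termini are constructed so
  no prefix equals the reverse complement of its suffix, which would
  make the planted breakpoint intrinsically ambiguous;
- a 5-gene sulfate-cluster mimic carrying 4× expression in the mutant;
- a "7806SL-mimic" third assembly with a planted 44,534-bp direct
  duplication, for the duplication finder.

Truth tables are written in the same conventions the callers emit
(left-normalized insertion calls spanning TSD + element), so
end-to-end recovery is asserted exactly. All randomness flows from one
seed through independent child streams per component, so resizing one
component does not perturb another; the same seed is byte-reproducible.

Expression tables draw per-gene lognormal baselines (meanlog 3.2,
sdlog 1.0 — a realistic right-skewed TPM distribution), multiply the
carrier strain by each planted effect, apply multiplicative replicate
noise at CV 0.1, and renormalize every sample to one million; the
planted effect mass is a small fraction of the transcriptome, so
renormalization distorts ratios negligibly.

What the fixture does **not** emulate: sequencing error and assembly
gaps (all copies are literally identical, so exact-mode counting is
guaranteed to succeed — real diverged families exercise the
approximate mode instead), genuinely nested or tandem element
insertions, inversions mediated by *inverted* repeats, compositional
heterogeneity (GC skew, codon bias), and count-level sampling noise in
expression (TPM noise is modeled directly). Passing the planted-truth
suite therefore demonstrates the callers' correctness under their
stated models, not robustness to assembly artifacts.

Two constructed single-locus instances accompany the fixture:
`make_split_cds_example` (a 1,044-nt CDS/347-aa product interrupted
after codon 286 by a 195-nt block engineered to yield 286-aa and
64-aa products, the downstream stop sitting off-frame in the CDS tail)
and `make_extension_example` (a stop-ablating insertion extending a
900-nt CDS by +81 nt — the codon-multiple closest to the ~80-nt
extensions annotation pipelines report). Both are synthetic stand-ins,
deterministic, and validated at construction time.

## Problem sizes and runtime

The default test suite runs the 120-kb fixture for most checks and the
1-Mb pcc7806-mimic fixture once for the planted-recovery acceptance
check (~100 s total on one CPU). `scripts/acceptance.py` runs the
1-Mb fixture plus the statistical calibrations (20 seeds × 2,000-gene
null tables; 20 seeds × both replicate depths for recall) in about a
minute. Memory stays under ~2 GB, dominated by the k-mer dictionaries
on the 1-Mb pair. The same code runs unchanged on 5-Mb assemblies in
minutes.

## Known limitations

- Exact-copy repeat mining will fragment a family whose copies are not
  literally identical; use the catalog matcher at relaxed identity for
  diverged families.
- The anchor model assumes assemblies of the same strain lineage;
  below ~99% genome-wide identity, unique-k-mer anchors thin out and
  gap classification degrades toward "complex".
- Inversions are detected only when breakpoint-adjacent sequence is
  anchored; an inversion nested entirely inside a repeat is invisible.
- find_self_duplication reports direct duplications only.
- The expression module consumes TPM tables; it does not model counts,
  so it inherits TPM's compositional coupling between genes.
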