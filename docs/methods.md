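# Methods

## Data model and coordinate conventions

All coordinates are 1-based and both-ends inclusive (GenBank
convention); a feature of length L spans `start..start+L-1`. The J
(majority) strand is the deposited/plus strand, N its complement.
Features never wrap the replication origin; on the standard lepidopteran
layout the control region is the terminal block of the circle
(15,316–15,721 on the bundled annotation), and the wrap junction back to
trnM is reported with its true signed gap (0 on that layout).

Feature tables may carry printed `Length` and `Intergenic nucleotides`
columns. Both are *ignored for computation* — coordinates are
authoritative and the derived columns are recomputed — but printed
lengths are retained so validation can surface printed-vs-coordinate
conflicts. The bundled annotation has exactly one such conflict (nad4:
printed 1,338 vs coordinate length 1,339); the coordinates are used
everywhere, and only 1,339 makes the PCG total of 11,269 bp add up.
Thousands separators and Unicode minus signs are normalized on input;
output uses ASCII only.

## Composition and skews

AT skew = (A−T)/(A+T), GC skew = (G−C)/(G+C), computed on the J strand.
The ratio is scale invariant, so it applies equally to counts and to
percentages; when both terms are zero the skew is *undefined* and
reported as absent rather than 0 (0 would wrongly claim balance). N
bases are excluded from counts but kept in the region size; ambiguity
codes other than N are rejected rather than silently miscounted.

The "PCGs" block concatenates the 13 protein-coding genes in genomic
order using their **J-strand projections** — N-strand genes are *not*
reverse complemented. This is the convention under which the PCG block
of an insect mitogenome shows a strongly negative AT skew even though
every coding strand is A-rich, and it is the only convention consistent
with computing all skews "on the J strand". A `strand_mode=
"coding_sense"` switch selects the alternative. Overlapping genes
contribute their shared bases once per gene (plain concatenation), which
is what makes the block size equal the sum of gene lengths (11,269 bp on
the bundled annotation).

Internal arithmetic is at full double precision; rounding happens only
at report time, half-up (ties away from zero) to the conventional
printed precision — percentages 2 dp, skews 3 dp, genome fractions 1 dp.
Half-up is an assumption (report tables rarely state their rounding
rule); every reproduced value was also checked to be insensitive to it
at the printed precision except through the final digit.

## Codon usage

The genetic code defaults to NCBI translation table 5 (invertebrate
mitochondrial: AGA/AGG→Ser, ATA→Met, TGA→Trp; stops TAA/TAG), built from
Biopython's codon tables and overridable. Coding sequences are read in
coding sense (N-strand genes reverse complemented). Conventions, each
chosen to match common mitogenomics practice and all switchable or
visible in the API:

* Start codons are counted as read; the non-canonical CGA initiator of
  cox1 therefore stays in the Arg family rather than being remapped to
  Met. The audit reports it separately as a non-ATN start.
* Stop codons are tracked in `counts` but excluded from the sense-codon
  total that is the denominator of CDspT and from RSCU families.
* A trailing partial codon (an incomplete stop such as nad4's "TA",
  completed in vivo by polyadenylation) is excluded from all codon
  statistics and surfaced only by the audit. For a gene annotated with
  a 1–2 nt stop the audit compares the matching-length 3′ suffix, so an
  annotated "TA" is checked against the gene's last two bases.
* RSCU of a family with zero total is undefined and absent, not 0.

Invariants maintained (and property-tested): Σ CDspT = 1000 over sense
codons; Σ RSCU over each observed family equals the family size; pooled
counts equal a naive frame-0 3-mer tally.

## Architecture

Junctions are computed between consecutive features in start order,
strand-blind, including the wrap junction, so junction count equals
feature count and the circular conservation identity
Σ lengths + Σ spacers − Σ overlaps = genome length holds exactly on any
layout (this is an algebraic identity; the test checks the
implementation's bookkeeping, and it is exercised on 200 random
layouts). Multi-feature pileups are handled pairwise-consecutively only;
no transitive overlap merging. On the bundled annotation the coordinates
yield 8 overlapping junctions totalling 79 bp; the original study text
reports nine overlaps totalling 144 bp, a discrepancy the validator surfaces but
the package does not attempt to reconcile — coordinates win.

## Motif scanning

All scans run on the J strand of the annotated region (landmarks are
conventionally reported on the presented strand); `find_motif` allows
overlapping hits. The tandem detector reports each maximal perfectly
periodic tract exactly once: at its leftmost start, with the smallest
generating unit (requiring a primitive unit is equivalent to requiring
the tract's minimal period), counting only full copies. Mismatch-
tolerant repeats (Tandem Repeats Finder behaviour) are deliberately out
of scope: only perfect repeats are found. "Poly-T immediately follows
ATAGA" is defined as a gap of at most 2 bp, a tolerance chosen because
published control-region figures show adjacency without stating one.
The (AT)n reporting threshold is 5 copies by default; the canonical
(AT)10 call is exercised through synthetic planting.

## Synthetic genomes

Background bases are i.i.d. from probabilities solved from the target
A+T fraction `at` and the two target skews (s_AT, s_GC):
pA = at(1+s_AT)/2, pT = at(1−s_AT)/2, pG = (1−at)(1+s_GC)/2,
pC = (1−at)(1−s_GC)/2. Defaults are the study conditions: the published
38-feature layout (15,721 bp), at = 0.80, s_AT = −0.005, s_GC = −0.236.

PCG spans are overwritten with ORFs: the planned start codon (per-gene
defaults from the template annotation, hence CGA for cox1), interior
codons drawn from the 62 sense codons **weighted by the product of the
per-base probabilities**, and the planned stop ("TA" for nad4). Uniform
sense-codon sampling was rejected because it would drive coding regions
to ~50% A+T and the whole genome to ~58%, defeating the point of the
emulation; with composition-weighted sampling the realized genome-wide
A+T stays within 1% of target (the small residual comes from excluding
the two stop codons and fixing start/stop trigrams). Interiors are
resampled if truncation creates an in-frame stop. Where two PCGs
overlap (atp8/atp6 on the standard layout) the shared bases cannot
satisfy both genes, so planned start/stop trigrams are re-asserted in a
second pass; an occasional in-frame stop straddling the overlap is
possible and is logged as a warning, mimicking the imperfections of real
annotations. Realized whole-genome skews deviate from the targets
because reverse-complementing N-strand genes flips their skew
contribution — exactly the mechanism that shapes real mitogenome skews —
so skew convergence is tested on featureless circles.

Landmarks are planted last at fixed region-local offsets (ATAGA at 11,
20 T's at 16, (AT)10 at 61, 12 A's at 381 within the 406 bp control
region; ATACTAA at 8 in the 22 bp trnS2–nad1 spacer). Planting into a
coding span or another landmark is an error. For repeat landmarks a
flanking base is flipped when the random background would extend the
run, so planted coordinates are exactly recoverable. The poly-A run is
12 bp (longer than the ~7 bp longest random A-run expected in a 400 bp
A+T-rich region) so that it is the leftmost-longest run by
construction rather than by luck. One seeded generator (numpy
`default_rng`) drives all sampling; the ledger records the seed,
probabilities, planted coordinates and final base counts, and the final
counts always equal `composition()` of the emitted sequence.

What the emulation does **not** capture: codon-position-specific and
gene-specific composition heterogeneity, realistic tRNA/rRNA structure,
replication-driven skew gradients around the origin, and repeats with
mismatches. Passing plant-and-recover tests therefore demonstrates
correctness of the detectors and bookkeeping, not sensitivity on real
control regions.

## Problem sizes and numerical choices

Property suites run at sizes chosen to exercise the arithmetic
thoroughly while staying instant on a laptop: 200 random circular
layouts for the conservation identity, 100 random 400 bp A+T-rich
strings against the brute-force motif/tandem oracles, hypothesis-driven
cases (derandomized) elsewhere. Skew-target convergence is checked at
2 kb and 20 kb with tolerance 4/√(expected base count). Floating-point
identities (CDspT sum, RSCU family sums) are asserted to 1e−9; the
skew scale-invariance property to 1e−12.

## Known limitations

* GenBank name normalization covers the standard mitochondrial
  vocabulary and common aliases (COI/COX1, CYTB, ND4L, tRNA-Xxx with
  anticodon qualifiers); exotic labels are kept verbatim with a warning.
* Features spanning the origin are unsupported by design; annotations
  should place the control region terminally.
* The validator's canonical gene set is the 37-gene metazoan complement;
  taxa with duplicated or lost genes will produce findings that are
  informational, not errors.
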