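# Methods

This package re-implements, as a reusable pipeline, the computational side of
a resistance-gene allele-mining campaign: selecting candidate accessions from
a germplasm panel through a screening funnel, characterising an allelic
series relative to its consensus sequence (SNPs, indels, polymorphic blocks
and their donors), and summarising nucleotide diversity and the
non-synonymous/synonymous substitution balance per protein domain.  Every
stage can be exercised end-to-end on synthetic allelic series with recorded
ground truth, so the pipeline is testable without any sequence downloads.

## The gene model

The system modelled is a CC–NBS–LRR resistance gene of 4442 bp: two exons
separated by a 200 bp intron, spliced CDS of 4242 bp, partitioned into the
coiled-coil region (474 bp), the nucleotide-binding-site region (1062 bp),
an interspacer (198 bp) and 28 leucine-rich repeats (2508 bp in total;
474 + 1062 + 198 + 2508 = 4242).  Only the four top-level domain lengths are
fixed by the architecture; the internal LRR_1..LRR_28 boundaries are not
published, so `default_domain_map(split_lrr=True)` slices the LRR region into
28 near-equal parts and marks them approximate — users with real repeat
annotations supply their own map.  The exon-1 length (the intron junction
position) is likewise configuration; the default places it at CDS position
966.  All genomic coordinates are 1-based inclusive in reference (consensus)
coordinates; domain coordinates are 1-based CDS positions.

Alleles whose structure cannot support a full-length open reading frame — a
frameshifting indel, or a deletion that removes an exon/intron junction — are
flagged as putative pseudogenes and excluded from all coding statistics.

## Alignment and consensus

True alleles of such a series exceed 97% pairwise identity; cluster paralogs
sit near 83–88%.  For this regime the package aligns by a center-star
strategy: each sequence is globally aligned to a designated center (the
`role=reference` sequence, else the first) with an affine-gap aligner
(match +1, mismatch −2, gap open −8, gap extend −1; Biopython's
`PairwiseAligner` provides the Gotoh machinery), and per-center-position
insertions are merged into shared columns.  The test suite checks the
pairwise scores against an independent full-DP implementation on sequences up
to 200 bp.  Pre-computed alignments are accepted as gapped FASTA and only
validated and indexed.  This is not a general-purpose MSA: for inputs far
below 80% identity a warning is emitted and a dedicated aligner should be
used upstream.

The consensus is the per-column majority base over the selected rows, with N
treated as missing.  Ties are broken lexicographically (A<C<G<T) and
reported; a column is gap in the consensus only when gaps strictly outnumber
every base, and such columns carry no reference position.  Because variant
polarity, block coordinates and the diversity denominators all live on the
consensus, the consensus row is prepended to the alignment and all
coordinate maps derive from it.

## Variant calling and effects

Variants are consensus-relative: one SNP per mismatching column, one indel
per maximal gap run, N producing no call.  Indels are left-normalised against
the ungapped consensus, but a shift is refused when it would collide with
another record of the same allele, so applying an allele's record set to the
consensus always reconstructs the allele byte-for-byte (a property asserted
on simulated data).  SNP effects substitute the alternative base into the
consensus codon — the other two codon positions stay at consensus state even
when the allele carries further changes there; joint codon effects are
handled by the diversity module's pathway averaging.  Indels within the CDS
are frame-preserving iff their length is a multiple of three; a deletion
removing a splice junction is structure-disrupting regardless of length.

## Polymorphic blocks and donor attribution

Gene-conversion and recombination footprints appear as dense clusters of
polymorphisms.  Blocks are segmented greedily left-to-right: a site joins the
open cluster when it lies within `max_gap` (default 250 bp) of the previous
site, and clusters of at least `min_sites` (default 3) become blocks.  The
published figures draw blocks without stating formal criteria; these defaults
were chosen so the described blocks (11, 8 and 43-site examples spanning tens
of bp up to several LRRs) would cluster, and both parameters are exposed.

A donor "shares" a block site when it carries the identical non-consensus
base at the homologous column — co-polymorphism with a different base does
not count.  Indel members and columns where the donor has a gap or N are
excluded from the shared/total counts.  Blocks are classified per donor as
identical (100% shared), partial (≥40%, configurable) or unique.  Because the
published sharing count for one allele is ambiguous between a block reading
and a fixed window reading, a window-query mode
(`window_shared_sites(alignment, allele, donor, (start, end))`) is provided
alongside block matching.  Chimera reports name, per allele, the consensus
backbone and the best donor(s) per block, ties listed in id order, with
paralog-derived blocks flagged.  The ploidy profile canonicalises block
footprints (sets of (position, alternative base) pairs) by multiplicity,
counts an allele as a carrier when it shares at least half of a footprint
(so partially overwritten tracts still register), and flags footprints whose
carriers sit in exactly one ploidy group.

Statistical significance of conversion (GENECONV-style permutation tests)
and recombination-rate estimation are out of scope.

## Diversity statistics

Per region and group the package reports:

* **Segregating sites** under complete deletion: columns with ≥2 distinct
  non-gap, non-N bases, columns with any gap excluded.
* **Sites per 100 bp** against both the ungapped reference length and the
  gapped alignment span, since published tables of this kind do not always
  state the denominator; both are in the output.
* **π**, the mean over unordered sequence pairs of differing/compared sites
  with pairwise deletion.  A second, explicitly labelled `plugin` estimator
  divides the same pair sum by n² (the expected heterozygosity of the
  observed frequencies).  The two differ by the factor (n−1)/n; the plugin
  form is exactly invariant under duplicating the whole panel, while the
  sample π rescales by 2(n−1)/(2n−1) — a deterministic reweighting, not new
  diversity.  The sample π is the default and matches the all-pairs
  brute-force oracle in the tests.
* **Ks and Ka**, counts of synonymous and non-synonymous segregating changes
  relative to the group consensus: one change per distinct (site, minority
  base); codons with several changes are resolved by equal-weight averaging
  over all substitution orders, fractional tallies rounded half-up at the
  end.  The reported ratio is the plain count ratio Ka/Ks — the convention
  that reproduces the published table cells — not a per-site rate; a
  site-normalised Nei–Gojobori pN/pS with Jukes–Cantor correction is
  available under an explicit method label.  Codon-model maximum-likelihood
  dN/dS is out of scope.

Printed values are truncated (floored) to two decimals; the published cells
themselves show truncation (e.g. 38/16 = 2.375 printed as 2.37), and rounding
is exposed as an option.  A guard of 1e-9 is added before flooring so exact
decimal inputs are not pushed down by binary representation.

## The screening funnel

Accessions pass six stages: (1) panel membership; (2) resistant (R) or
intermediately resistant (IR) to at least one isolate of the configured
panel; (3) locus presence by an STS marker; (4) no hit for any known
functional allele; (5) candidacy, which requires full R — intermediate
resistance suffices to enter molecular screening but not to nominate a
candidate; (6) sequence obtained.  Sequencing failure is an input field, not
predicted.  The per-country report validates monotonicity along the funnel
and that totals equal column sums.

In-silico marker genotyping matches the forward primer on the plus strand
and the reverse-complemented reverse primer downstream, each within a
configurable mismatch budget, and accepts products within ±25% (default) of
the expected length.  Real primer sequences for the 946 bp diagnostic assay
are not published in the source campaign, so the shipped fixtures use
synthetic primers with the same geometry; marker results can also be supplied
as precomputed booleans in the accession table.

Obtained sequences are classified against the consensus and a panel of known
susceptible variants by exact variant-set identity: `consensus_identical`,
`known_susceptible_variant`, or `novel`.

## The synthetic-data generator

The generator emulates the study conditions: an ancestral 4442 bp gene with a
clean ORF; alleles derived by (in order) donor-copied conversion tracts,
sparse SNPs, optional in-frame 3 bp indels, and an occasional 302 bp
junction-spanning deletion (the pseudogene case, 4442 → 4140 bp); and a
paralog pool with substitution-only divergence drawn uniformly from the
0.117–0.166 mismatch band.  Defaults: Poisson(6) SNPs per allele with a 0.72
non-synonymous fraction (matching a combined Ka/Ks count ratio near 2.6 in
expectation, via rejection sampling), Poisson(0.8) tracts per allele with
geometric lengths of mean 300 bp (the true tract-length distribution is
unknown; the published blocks span tens of bp to several LRRs, and the
distribution is configurable), 3 bp indel probability 0.12, pseudogene
probability 0 unless requested.  Tract donors default to the paralog pool so
tracts carry diagnostic sites; later SNPs may overwrite tract sites, which is
what produces partially shared blocks.  Every event is recorded in a truth
object whose replay reconstructs each sequence exactly.

Accession panels come in two modes: exact margins (per-country stage counts
are hit exactly, with known-allele hits and sequencing-outcome classes dealt
from configured distributions — the packaged demo panel uses the campaign's
published margins, 733 accessions over 20 countries with stage totals
733/154/109/81/51/41) and random mode with per-stage pass probabilities.
Phenotypes in the panel are assigned deterministically from the stage a
record must reach — a modelling convenience, not a claim about infection
biology.

What the simulator does **not** model: phylogenetic structure among alleles
(no coalescent), selection dynamics, sequencing error, heterozygosity, or
mosaic donors within a single tract.  Passing the recovery tests therefore
shows that the pipeline's logic is correct under clean, known-truth
conditions; it does not certify performance on real trace data or on series
whose block structure violates the tract model.

## Recovery evaluation and problem sizes

`allelemine.evaluation` runs replicated simulate → align → call → segment →
match experiments and tallies: exact SNP recovery per allele (injected SNPs
that the simulation later deleted are excluded; extra calls inside tract
spans are donor-diagnostic sites and extra calls inside deleted spans are
gap-placement representation artifacts, so neither counts against recovery);
donor attribution for tracts with at least 3 *surviving* diagnostic sites
(later events can overwrite a tract, in which case the surviving sequence
genuinely derives from the later donor), counting an attribution correct
when the true donor is among the equal-best matches; and pseudogene-flag
errors in both directions.  The replicated experiment uses 50 seeded
replicates of 4 alleles + 2 paralogs over the full 4442 bp gene — a panel
size chosen to keep the experiment a desk-scale computation while exercising
every event type; attribution accuracy is insensitive to the panel size in
our runs (≈90–96% across seed bases, always ≥90% with ≥180 evaluated
tracts).

## Numerical and tie-break conventions

* Consensus ties: lexicographic base order, reported per column.
* Donor ties in block matching: all equal-best donors listed, id order.
* Indel left-normalisation stops at occupied positions (round-trip safety).
* Region Ka/Ks requires codon-aligned region boundaries (the default domain
  map is codon-aligned by construction); non-aligned custom regions are
  rejected rather than silently re-framed.
* Degenerate inputs: empty groups, single-member groups for π, zero-length
  denominators, inconsistent funnel margins and malformed primers all raise
  with specific messages rather than returning sentinel values.

## Known limitations

* The center-star aligner guarantees optimal pairwise scores against the
  center, not a globally optimal MSA; for the near-identical inputs it is
  built for this is immaterial, and gap placement identical to any external
  GUI aligner is not promised.
* Count-based Ka/Ks has no variance model; use the labelled pN/pS variant
  (or an external codon-model tool) when site normalisation matters.
* Block segmentation is a heuristic with two parameters; blocks produced by
  overlapping conversions from different donors are attributed to the
  majority donor.
* The diversity table from real campaign sequences requires the deposited
  accessions, which this package does not download.
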