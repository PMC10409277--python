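# Methods

This note documents the models, defaults and numerical choices behind
`numtscan`, and what the synthetic-data experiments do and do not show.

## The generative model

A *genome system* consists of a linear mtDNA reference, a plastid (pt)
sequence, and one nuclear genome per simulated line. Lines share nuclear
chromosome backbones and differ only through planted numts — modelling
numt presence/absence polymorphism between closely related lines while
holding everything else fixed. Planted features are:

- **mt repeat** — an mtDNA interval copied to a second mtDNA location;
- **pt-homologous block** — an mtDNA interval copied into the pt sequence;
- **numt** — an mtDNA interval copied into one line's nuclear chromosome,
  with explicit divergence edits (substitutions, insertions, deletions, so
  e.g. an internal tandem duplication is representable);
- **true heteroplasmy site** — an mtDNA position carrying an alternative
  allele at frequency f ∈ (0, 1). Sites sharing a *molecule class* are in
  coupling phase: one Bernoulli(f) draw per fragment decides whether the
  whole fragment comes from the variant molecule class.

Features replace the host interval rather than inserting, so backbones stay
aligned across lines; ground truth (coordinates, edits, frequencies) is
carried on the system and serializable as TSV.

### Read simulation

Paired-end fragments pick a host with probability proportional to
`copies × (length − mean_insert + 1)`. The effective-length factor (rather
than raw length) is deliberate: fragment starts are uniform over the
`L − insert + 1` admissible positions, so weighting by raw length would
under-cover hosts not much longer than the insert and bias the copy-ratio
law at desk scale; with effective lengths, interior per-bp coverage is
proportional to copy number exactly, and the two conventions converge as
L ≫ insert. Defaults (study conditions): 150-bp mates, 350 ± 35 bp
inserts, mtDNA:nuDNA copy ratio 50:1 (middle of the 40–60:1 leaf-tissue
estimate), ptDNA:nuDNA 500:1 (plastid DNA in large excess; at ~1,000×
mtDNA depth this pushes pt-homologous coverage past the 10,000× depth
flag), substitution-only sequencing errors at 0.2% per base, constant
placeholder base quality (Q37; quality trimming is upstream preprocessing
and not modelled). mtDNA circularity is off by default — coordinates stay
linear, matching how reference positions are quoted.

With a single-copy numt identical to its cognate mtDNA interval, the
expected nuclear-origin share of reads over an *interior* cognate window is
1/(r+1) ≈ 2% at r = 50. The interior qualifier matters: fragments
straddling a numt boundary map only partially (or not at all) onto mtDNA,
so windows within one read length of the boundary under-count nuclear
reads. This is a genuine property of mapping, not an artifact; the
copy-ratio checks therefore measure windows ≥ one read length inside the
numt, where mapping-efficiency parity holds.

## Homology search and the eight-category partition

Local homologies are found by exact k-mer seeding (k = 15, both strands),
greedy chaining of seeds on nearby diagonals (diagonal band 20 bp, query
gap ≤ 60 bp), ungapped X-drop extension of the chain ends (match +1,
mismatch −3, drop 12), and identity refinement of the final interval by a
global edit-distance alignment (identity = 1 − distance / max span).
Alignments shorter than `min_len` (default 100 bp — homologies must be
100 bp or longer) or below `min_identity` (default 0.80) are discarded;
on self-comparison the trivial identity diagonal is excluded. Boundaries
are the maximal-scoring extension ends — deterministic and testable, in
place of manual inspection of alignments. Contained duplicate hits are
suppressed. The unit tests verify boundaries and identities against an
exact Smith–Waterman dynamic-programming oracle on ≤10-kb instances.

Each mtDNA position then carries three booleans — covered by a self hit, a
nuclear hit, a plastid hit — defining categories 1–8 (category 2 = none of
the three). Overlapping hits are unioned per evidence class before
classification. Summaries derive every aggregate from the same
per-category totals: repeated bp = Σ{1,3,5,7}, single-copy = Σ{2,4,6,8},
nuclear-homologous = Σ{3,4,7,8}, plastid-homologous = Σ{5,6,7,8}, unique =
Σ{1,2}; percentages are reported to the nearest 1%. On the published sugar
beet totals these aggregates reproduce 76,749 / 292,052 / 256,797 / 8,753
bp; note the published prose total of 111,759 bp unique sequence differs
by 3 bp from the sum of its published categories 1+2 (111,756) — this
package always reports the sum of its own categories.

The depth-based plastid flag (positions with mapped depth strictly greater
than 10,000) is computed separately from the alignment-based flag and the
two are only combined on explicit request, since how the two criteria were
historically combined is not documented.

## Tiling presence/absence scan

"Every 50-bp sequence" is read as consecutive non-overlapping tiles
(step = 50, configurable down to 1); a terminal remainder below 20 bp is
merged into the previous tile to avoid spurious matches on tiny queries,
so a 368,801-bp reference yields 7,375 50-bp tiles plus one 51-bp tile. A
tile is positive for an assembly when an alignment covering the whole tile
reaches identity ≥ 0.90 (identity = 1 − edit distance / tile length, both
strands searched). This criterion is monotone in the threshold and
independent of assembly processing order. Consecutive positive tiles
(bridging ≤ 1 negative tile) merge into numt-homologous intervals; size
statistics use mean rounded to the nearest bp, smallest mode on ties, and
the lower-middle median on even counts (interpolation available); numt
intervals whose subject-side neighbours lie within 5 kb share a cluster,
and singleton clusters are flagged solitary.

## Read mapping and site extraction

The built-in mapper is a deliberately small stand-in for a production
aligner, sufficient for desk-scale synthetic data: exact 21-mer seeds at
21-bp offsets on both strands propose candidate placements, each verified
by a bounded edit-distance alignment (≤ 12 edits) in a padded window; the
lowest-distance placement wins with deterministic tie-breaking (smaller
position, then forward strand). Alignment ends are then soft-clipped to
the maximal-scoring stretch of columns (match +1, mismatch −4, gap −6,
minimum 25 retained matches) — local-aligner behaviour that prevents reads
crossing a homology boundary from depositing their non-homologous overhang
as spurious mismatches just outside the boundary.

Base composition counts A/C/G/T per position over all covering reads;
insertions are counted at the anchor position left of the event, deletions
at every deleted position, and total depth includes deletion evidence. A
site is called intra-individually polymorphic when some non-reference
allele reaches **both** a fraction ≥ 1% of total coverage and ≥ 10
supporting reads, thresholds applied per allele (every qualifying allele
is listed; the site counts once). The 10-read floor interprets the
published "~10 reads" guard; during development, coincident sequencing
errors at 0.2% per base occasionally produced isolated ≥1% alleles with
5–9 reads at ~1,200× depth, so the floor is doing exactly the artifact
suppression it was designed for. Zero-depth positions are skipped and
counted in the log. SAM/BAM from external mappers is accepted (header
reference length is validated; optional same-coordinate deduplication for
files that still contain PCR duplicates).

## Phasing and numt attribution

Sources spanning ≥ 2 variant positions (reads, or cloned PCR products —
one code path, clones being long error-free sources) contribute allele
strings with a gap token at uncovered positions and a one-character
deletion token, keeping string length equal to the number of positions.
The verdict is *coupling* when ≥ 95% of informative sources are
homogeneous (all-reference or all-variant), *repulsion* when ≥ 95% mix
reference and variant alleles, *mixed* otherwise; having no informative
source is an error distinct from *mixed*. The 95% cut-off is a package
decision (clone evidence in the motivating study was qualitative) and is
configurable.

Variant haplotypes are matched to candidate numts by aligning the numt to
the cognate reference window (global edit-distance alignment) and
comparing residues at each variant position; positions in alignment gaps
count as unmatched and are flagged. Numt-private differences outside the
variant positions (substitutions, indel events) are also reported, since a
perfect residue match with private edits still distinguishes the numt from
the mitochondrial variant class. When the optimal alignment is ambiguous
(e.g. a long deletion through low-complexity sequence), private-edit
counts reflect one optimal path.

## In-silico PCR–RFLP and the segregation test

Amplicons are the shortest intervals from an exact forward-primer match to
the nearest downstream reverse-complemented reverse-primer match, both
strands searched, mismatch tolerance configurable (default exact); absence
of a product is a result ("no amplification", the expected outcome for a
line lacking the numt allele), not an exception. Digestion places cuts at
each IUPAC-motif occurrence (within-site cut offset configurable but
irrelevant at gel resolution); n sites give n+1 fragments whose lengths
always sum to the input length. Genotyping compares band patterns under a
5% co-migration tolerance (agarose resolution): the union of both parental
patterns scores heterozygous, a single parental pattern homozygous,
anything else unscorable.

The segregation test is an exact multinomial goodness-of-fit test: the
p-value sums, over all genotype-count outcomes with the observed total,
the probabilities of outcomes no more probable than the observed one under
the hypothesized ratio (default 1:2:1). It is computed in exact integer
arithmetic — outcome weights `multinom(n; a,b,c) · r₁ᵃr₂ᵇr₃ᶜ` are compared
as integers, so there are no floating-point ties — and enumeration is
cheap for n up to a few hundred. A chi-square (df = 2) value is reported
alongside, because published segregation analyses often quote an
unspecified "exact test": for the motivating F2 counts (1, 10, 5) this
package computes p_exact = 0.221 and p_chisq = 0.223, while the published
analysis quoted p = 0.49 from an unstated construction; the published
number is kept as a comparison constant and not asserted anywhere. Under
repeated true-1:2:1 sampling at n = 16 the exact test rejects at α = 0.05
in ≲ 5% of replicates (discrete exact tests are conservative); the suite
checks ≤ 6% over 10,000 replicates.

## Problem sizes used in tests and acceptance runs

The shared end-to-end system uses a 12-kb mtDNA reference, 2-kb pt, one
30-kb nuclear chromosome per line, a 1-kb numt with 12 interior divergent
substitutions, 12 coupling-phase 5% heteroplasmy sites, and ~1,200× mtDNA
depth (≈115k reads); copy-ratio measurements use a 6-kb mtDNA reference
with a 3-kb identical numt at 1,200–2,000× depth (≈40k reads over the
measured window, putting 3 binomial SE well inside ±0.3 percentage
points). These sizes were chosen so every stochastic check has comfortable
statistical margin while the whole suite stays fast enough to run
routinely.

## What the synthetic data does not show

The simulator draws uniform random backbones and i.i.d. substitution
errors: no GC bias, no Illumina error profile, no PCR duplicates, no
mapping-quality modelling, no low-complexity or repetitive genomic
context beyond the planted features. Passing tests therefore demonstrate
the *logic* of the pipeline — copy-ratio arithmetic, reference-dependent
masking, phase recovery, Mendelian segregation — not its robustness to
real-genome complications (mosaic numt clusters, nested repeats,
organellar recombination). Variant-caller comparisons and analyses
requiring real sequencing reads or real assemblies are out of scope.
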