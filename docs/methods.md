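# Methods

This note records the models, conventions and numerical choices behind
each analysis stage, what the synthetic data emulate (and do not), and
the known limitations.

## Coordinates and genome model

All genome coordinates are 1-based inclusive. The molecule is circular by
default; a feature with end < start wraps the origin and its length is
(L − start + 1) + end. When a feature table carries no sequence, the
genome length is taken from an explicit length if given, else from the
maximum end coordinate — in the canonical 37-gene fish arrangement the
last tRNA ends at the genome terminus, so the terminal coordinate is the
genome length. Ambiguity codes other than N are rejected; N is accepted
but excluded from every composition denominator.

Gene names are normalized to one lexicon (nad1…nad6/nad4l, cox1–3, cob,
atp6/atp8, rrnS/rrnL, trnX, CR, OL) through an editable mapping file
shipped as package data (`data/gene_names.tsv`).

## Composition and skews

AT-skew = (A − T)/(A + T); GC-skew = (G − C)/(G + C). A zero denominator
makes the skew undefined (reported as None/blank, never 0). Per-gene rows
of the region report are computed on the gene's **sense strand**, so the
light-strand gene *nad6* shows its characteristic negative AT-skew and
positive GC-skew as a property of its own coding sequence; a flag
switches to heavy-strand framing for cross-checks. Percentages are
reported to two decimals, rounded half away from zero.

## Codon usage

Reading frames start at CDS position 1. A trailing 1–2 nt remainder is an
incomplete stop (completed to TAA by polyadenylation in vivo); it is
annotated but never counted as a codon. Two total-codon conventions are
reported side by side: total PCG nucleotide length divided by 3 (the
convention that makes the canonical 11,439 bp of protein-coding sequence
equal 3,813 triplets), and the stricter count of complete non-stop
codons. RSCU families are the synonymous sets of the genetic code in
force (default table 2); amino-acid usage pools Leu and Ser across their
two codon boxes. Stop codons are excluded from counts and RSCU.

## Architecture

Overlaps are intersections of closed intervals on the circle, reported
for every intersecting pair (three-way overlaps appear pairwise);
touching features do not overlap. Overlap motifs are reported in the
heavy-strand frame regardless of the member genes' strands, which keeps
the report well-defined when the two genes sit on opposite strands (the
conserved *nad5*/*nad6* overlap mixes strands). Spacers are maximal
uncovered gaps, circular-aware. The control region is an explicitly
annotated CR feature if present, else the longest spacer of at least
200 bp, with a warning when its flanks are not *trnP*/*trnF*. Arrangement
comparison uses signed circular gene orders: identity is equality up to
rotation, and breakpoints count adjacencies of one genome absent from the
other (an adjacency (u,v) is equivalent to (−v,−u)).

## Control-region blocks and stem-loops

Conserved sequence blocks are called from an alignment of control
regions. Each column is scored by majority-base frequency with a
gap-inclusive denominator; a sliding window (default 15 columns)
qualifies when its mean score reaches the identity threshold (default
0.85) and its mean gap fraction stays at or below 0.2. Qualifying windows
are merged; block ends are then trimmed to columns that individually meet
the threshold (so boundary windows cannot drag in flanking background
columns); blocks shorter than 12 columns are dropped, and survivors are
numbered CSB-I… in coordinate order. Naming is positional, not
homologous: no claim is made that CSB-I here corresponds to the canonical
vertebrate CSB-1. The defaults were chosen so that blocks of the size and
conservation seen in percomorph control regions (~20 bp, near-invariant
across a family) are recovered as single blocks against a background of
ordinary control-region divergence; all four knobs are exposed.

The stem-loop finder enumerates all inverted repeats with stem ≥ 5 bp and
loop 3–20 nt (exhaustive; intended for replication-origin-scale regions
up to a few hundred bp), keeps only maximal ones (no outward or inward
extension possible within the mismatch budget), and ranks by (G–C pairs,
stem length) descending. Only exact Watson–Crick pairs count; G·U wobble
pairs are not scored, because stem stability in these origins is
conventionally described by G–C pair counts.

## Alignment and trimming

Pairwise and profile alignment use an affine-gap Gotoh dynamic program (a
gap of length k costs open + k·extend; defaults +1/−1/−5/−1) with a fixed
traceback preference (diagonal, then vertical, then horizontal), making
tied optima deterministic. Progressive alignment builds a UPGMA guide
tree from pairwise p-distances over canonically sorted labels and merges
profiles leaf-to-root with average-of-pairs column scores, so the result
is invariant to input order. Block trimming classifies columns by
majority-base fraction (conserved ≥ 0.5 of rows, flank-grade ≥ 0.85,
gap-containing columns never retained under the default gap policy),
splits at nonconserved runs longer than 8, trims segments to flank-grade
ends, drops blocks under 10 columns, and returns the retained original
column indices so provenance is verifiable. Retained columns are never
reordered or edited.

## Phylogeny

Distances: p, JC69 (d = −¾ ln(1 − 4p/3)) and K2P, with pairwise deletion
of gap/N sites (complete deletion available); saturated pairs raise an
error naming the pair rather than returning a silent infinity. Tree
inference is Saitou–Nei neighbor joining with the Q-criterion, ties
broken toward the lowest-index pair, and negative branch lengths clamped
to zero with a warning. Bootstrap support resamples columns with
replacement, re-estimates the NJ tree per replicate, and reports the
percentage of replicates containing each internal bipartition of the
point-estimate tree; with no variable columns supports remain undefined.
Likelihood-based tree inference (ML model selection, Bayesian MCMC) is
deliberately out of scope: the claims this package is built to evaluate
are topological (clade membership and monophyly), and a distance method
with bootstrap measures exactly that at desk scale. Trees are inferred
unrooted; outgroup rooting is a display operation.

## Selection

`slac` is a counting test in the Suzuki–Gojobori lineage. Per site:

1. Ancestral codons by parsimony over the 60 sense codons (Hartigan-style
   vote counting, exact also at multifurcations; ties resolve to the
   lexicographically smallest codon, and the number of ambiguous choices
   is recorded).
2. Observed substitutions per branch from endpoint codon pairs; changes
   of 2–3 nucleotides are averaged with equal weight over all shortest
   mutational pathways that avoid stop codons (pathways through stops are
   discarded). Total counts per branch always equal the endpoint Hamming
   distance.
3. Expected synonymous/nonsynonymous sites per codon by per-position
   neighbor enumeration. Changes into stop codons are excluded from both
   numerator and denominator (a flag switches to counting them as
   nonsynonymous); ES and EN are averaged over the parent and child
   codons of each branch, weighted by branch length, so ES + EN = 3 up to
   positions whose every change is stop-bound.
4. dN = ON/EN, dS = OS/ES; significance from a two-tailed binomial test
   of ON among ON + OS trials against the neutral expectation
   EN/(ES + EN). This replaces the extended counting-test tail
   computation and is an approximation — with fractional pathway-averaged
   counts the observed value is bracketed by floor/ceiling tails.

Endpoint counting cannot see multiple hits: on a branch-site carrying two
or more events (including reversals) the truth log and the counted values
legitimately differ. The simulator's log makes this precise, and the
cross-validation tests assert exact agreement on single-hit branch-sites
plus the Hamming conservation identity everywhere.

`fel_lite` fits, per site, synonymous and nonsynonymous rates (α, β)
under a codon model with equal nucleotide exchangeabilities and uniform
codon frequencies on a fixed tree (pruning likelihood over the 60 sense
codons; the symmetric generator is diagonalized once per evaluation).
The null ties β = α. Because β = α is an interior point of the free
two-rate alternative, the likelihood-ratio statistic is referred to a
plain χ²₁ — halving, appropriate only for boundary-constrained
alternatives, would double the false-positive rate. Calibration: under a
model-matched neutral simulation (κ = 1) the empirical false-positive
rate at α = 0.05 is ~6% at 200 sites; under strong transition bias
(κ = 4) the equal-exchangeability model is misspecified and rejects
~9–10%, which is why the counting test is the default method and the
likelihood test is labelled a simplified complement. Estimated rate
ratios at small event counts are noisy and their median is biased
downward; direction (β < α under purifying selection) is the reliable
readout.

## Synthetic data

`make_genome` emulates the holocentrid-style mitogenome: the 37-gene
arrangement, sizes, strands, start/stop classes, inter-gene gaps, and the
three conserved protein-gene overlaps of the shipped reference
annotation, with configurable A+T content (default 54.7%, the clade-scale
average), skews (defaults +0.08 / −0.26, typical heavy-strand values for
teleost mitogenomes), control-region length (default 862 bp within the
838–960 bp family range), five seeded control-region blocks whose
compositions echo the distinctive published block compositions (T/A-rich,
AT+C, T/C-rich, 70% C, A/C-rich), and a WANCY-cluster hairpin with a
configurable number of stem G–C pairs (default 8, the *Myripristis*
state; 7 for the other genera). Composition targeting samples bases from
the target distribution and then polishes by single-base flips at
unlocked positions (stop-safe inside coding sequence), reaching the
target within ±0.5 percentage points.

Where the published overlap motif and the published start/stop
annotations collide — the 10 bp atp8/atp6 overlap cannot simultaneously
carry the printed motif, an ATG at the atp6 start and a TAA at the atp8
stop — the start/stop codons win and the overlap length is realized
exactly; the nad4l/nad4 and nad5/nad6 motifs are internally consistent
with the annotation and are reproduced verbatim.

`evolve` is a codon-space continuous-time simulation: single-nucleotide
codon changes at rate κ-weighted for transitions, multiplied by ω when
nonsynonymous, zero into stops, normalized so that one unit of branch
length is one expected substitution per codon site at ω = 1. Every event
is logged (branch, site, from/to, syn/nonsyn). There are no indels: no
analysis stage here requires gap realism beyond what alignment of
equal-length sequences exercises, and gap-free truth keeps the counting
cross-validation exact. `make_study_set` evolves the 13 protein genes in
codon space (start/stop and overlap codons frozen) and everything else at
nucleotide level (control region at 3× rate with the seeded blocks and
the hairpin frozen) along a known tree with two reciprocally monophyletic
seven-taxon ingroup clades of two "genera" each plus three outgroup taxa.
Default ingroup ω = 0.1 (strong purifying selection, the regime real
mitochondrial protein genes occupy) and κ = 4.

What passing the synthetic suite does **not** show: performance on real
annotation noise (mispredicted gene boundaries), alignment of
length-variable control regions (the simulator is indel-free), base
compositional heterogeneity along the genome, or selection regimes with
among-branch variation. The reference-value registry
(`mitochar.reference`) records the published quantities that require the
deposited accessions (genome-length and composition ranges, the most-used
codon's RSCU, and the full-alignment selection site counts); these are
context for reports, not test targets.

## Problem sizes

Default problem sizes were chosen at desk scale: 100 bootstrap
replicates (configurable), a 17-genome study set (~16.5 kb each),
500-site simulations for rate recovery and 200-site simulations for
calibration checks. The acceptance script completes in well under a
minute on one CPU; the full test suite in about forty seconds.
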