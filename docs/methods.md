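# Methods

This note documents the models, conventions and numerical choices
behind `anserdiet`, and what the synthetic-data generator does and does
not emulate.

## Sequence distances and marker evaluation

**K2P distance.** For an aligned pair, sites where either character is
outside {A,C,G,T} (gaps, N) are deleted *pairwise* — each pair keeps its
own comparable sites, which is what makes per-group summaries comparable
across genes of different coverage. With transition proportion *P* and
transversion proportion *Q* over comparable sites,

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q).

When a log argument is non-positive the distance is *saturated*: the
estimator diverges. Saturation is propagated as an explicit flag, never
as an arbitrary large number; UPGMA refuses matrices containing
saturated pairs. This is deliberate — substituting a cap would silently
distort tree heights.

**Pairwise alignment.** Barcode sequences of near-equal length are
aligned globally with affine gaps: match +1, mismatch −2, gap open −5
(the first gapped base), extension −2, end gaps penalized. The scheme is
conventional for short organellar barcodes; the exact parameters matter
little for distances because gap/N columns are deleted pairwise anyway.
The alignment backend is Biopython's `PairwiseAligner` (C
implementation); its first optimal traceback is deterministic for fixed
inputs. Sets of equal-length sequences are treated as pre-aligned.

**Divergence summaries.** Inter-specific pairs within a genus or family
are pairs whose species labels differ. The dispersion term is the
*population* standard deviation over those pairs — a deliberate,
documented choice; with a handful of pairs the difference from the
sample SD is visible, so determinism and explicitness win. `intra_max`
is absent (not zero) when a group has no intra-specific pair, and the
barcoding-gap test then returns an explicit *indeterminate* rather than
false: "no evidence" is not "gap absent". The gap itself is strict:
min inter-specific > max intra-specific.

**UPGMA and Rf.** UPGMA is average-linkage agglomeration
(`scipy.cluster.hierarchy.linkage(..., "average")`); node heights are
half the merge distance, so cophenetic leaf-to-leaf distances equal the
linkage distances and any ultrametric input is reproduced exactly (to
floating-point round-off, checked at 1e−12). The resolution rate Rf is
the percentage of species whose leaves form a clade, computed over
species with at least two sequences; singletons are excluded from both
numerator and denominator because counting them as trivially
monophyletic would inflate Rf toward 100 on sparse libraries.

**Marker ranking** is lexicographic: amplification success first (a
marker that does not amplify cannot be rescued by divergence), then the
number of groups in which the marker attains the largest mean
inter-specific divergence, then the number of groups with a barcoding
gap, with alphabetical tie-breaks so the order is total and
reproducible. A per-criterion audit table is emitted alongside.

## Reference library

Identical sequences (exact string equality after upper-casing and U→T)
are collapsed into resolution groups; the assignable rank of a group is
species / genus / family as its members span one species, one genus, or
one family. Exact matching is the right notion here because the
downstream genus/family calls are driven by *identical* reference
sequences; near-identity collapsing would discard usable signal.
Sequences differing only by terminal length are *not* collapsed (they
are distinguishable in principle; differing amplicon trims can cause
this) but a warning is logged. Records with more than 5% N are rejected
with a warning. Multiple records per species are accepted; per-family
counts report distinct species and distinct sequences.

## Amplicon pipeline

**Merging** searches ungapped 3' overlaps of at least
`merge_min_overlap` (default 16) bases and takes the overlap with the
most matching bases (ties: longest), provided its mismatch fraction is
at most `merge_max_mismatch_frac` (default 0.05). In the overlap the
higher-quality base is called; the posterior quality is the maximum of
the two scores when they agree and their absolute difference when they
conflict, capped at Q41. Indel sequencing errors inside the overlap
cause rejection rather than a misaligned merge — the substitution-only
error model downstream depends on this.

**Demultiplexing** assigns a merged read to a sample only when it
begins with that sample's 8-nt tag plus forward primer and ends with the
reverse complements of the reverse primer and reverse tag. Tags match
exactly; primer positions match through IUPAC degeneracy sets. Reads
containing any N are discarded first; reads matching no sample, or more
than one (possible only with a malformed sheet), are counted in their
own discard categories. Tags and primers are then trimmed. Discard
categories are mutually exclusive so the conservation identity
`reads_in == assigned + sum(discards)` holds exactly and is asserted by
the pipeline runner at every stage.

**Quality filtering** keeps reads of at least `min_len` (default
100 bp, with exactly 100 kept) whose *mean* Phred score is at least
`min_qual` (default 30). The mean interpretation of "Q30" is the
default because a per-base minimum at Q30 would discard nearly all real
reads; both a `min` mode and an expected-errors mode (`ee`, at most 1.0
expected errors) are provided via `qual_mode` since the choice is a
genuine convention, not a fact.

**Clustering** is greedy centroid clustering at `otu_identity`
(default 0.98): uniques are scanned in abundance order (most abundant
variants found the centroids) and each joins the first centroid whose
global-alignment identity — matches over alignment columns, end gaps
penalized — reaches the threshold. End-gap counting is the conservative
choice for near-full-length amplicons. For equal-length pairs whose
ungapped identity is already ≥ 0.90, the ungapped alignment is optimal
under this scoring (a gap pair costs at least 10, more than the ≤ 10%
of mismatches it could repair at +3 each over these lengths), so the
column comparison is used directly; this is an exactness-preserving
shortcut, not an approximation. A post-hoc audit pass re-checks every
member against its representative. Chimera detection is not performed;
`run_pipeline` exposes a hook.

## Taxonomic assignment

Queries are aligned locally (Smith–Waterman, same scoring scheme) to
every reference on both strands — the library is dozens of short
barcodes, so exhaustive dynamic programming is cheaper than maintaining
a seeded search, and it cannot miss marginal alignments. Identity is
matches over alignment columns; coverage is *query* coverage (the
aligned query span over query length); subject coverage is also emitted
for audit since the convention is ambiguous in the field.

E-values use ungapped Karlin–Altschul statistics,
`E = K m n exp(-lambda * score)` with n the summed reference length.
Lambda is the positive root of `sum p_i p_j exp(lambda s_ij) = 1` under
uniform base frequencies; it exists iff the expected per-site score is
negative. K is computed from the lattice-case series

    K = delta*lambda * exp(-2*sigma) / (H * (1 - exp(-delta*lambda)))

with `H = lambda * E[S exp(lambda S)]`, `delta` the score-lattice span,
and `sigma = sum_k (1/k) (P(S_k >= 0) + E[exp(lambda S_k); S_k < 0])`
over binomially distributed k-site score sums, truncated when terms
fall below 1e−12. For +1/−2 this gives lambda = 1.333, K = 0.621,
matching published ungapped nucleotide values, and the formula was
additionally validated against direct simulation of maximal ungapped
segment scores. The gapped correction is not applied: with this library
any near-full-length match has an e-value around 1e−150, so the
identity and coverage thresholds dominate the decision regardless.

Thresholds are strict inequalities (identity > 0.98, query coverage >
0.98, e-value < 1e−50). Ties are the hits sharing the maximum score
after filtering; near-ties are *not* merged — the genus/family calls
this rule exists for are driven by exactly identical reference
sequences, which tie exactly. The lowest-common-ancestor rule then
returns the species when one remains, else the single genus containing
all tied species, else the single family, else an unassigned result
flagged `above_family`.

## Diet tables and method comparison

*Fs* for a taxon is 100 × (reads of OTUs assigned to it within the
group) / (the group's total *assigned* reads). Unassigned OTUs are
excluded from the denominator and reported separately; under this
convention each group's *Fs* column sums to 100 (±0.02 from rounding).
When a genus-level assignment coexists with species-level assignments
of the same genus, the genus row is labelled "X spp. (except …)" —
its reads are the residual that could not be placed in the listed
species; the same applies one rank up for families. Percentages are
stored as floats and rounded only at serialization (two decimals, half
away from zero).

The metabarcoding/microhistology comparison is rank-aware and
*consumed*: exact (taxon, rank) detections are matched first; among the
leftovers, a genus-level record in one method matches the other
method's congeneric species-level records, and a family-level record
matches leftover members of that family. Consumption matters: when both
methods report a genus-level record, those pair with each other, and an
additional congeneric species seen by only one method correctly remains
method-exclusive instead of being absorbed by the already-matched genus
record. The procedure is symmetric — swapping the inputs swaps the
"only" sets exactly. Species names absent from the reference taxonomy
fall back to binomial-prefix genus matching and are flagged.

## Synthetic data

`simulate_reference` draws a root sequence uniformly and walks a
balanced family/genus/species tree, applying a fixed number of random
substitutions per branch with a 2:1 transition:transversion bias
(K2P-like). Defaults — 250 bp, 5/10/25 substitutions on
species/genus/family branches — give congeneric identities around 96%,
comfortably below the 98% OTU threshold, which mirrors a usable barcode
on a local flora. Identical-sequence groups can be planted (congeneric
species sharing the genus ancestor; confamilial genera sharing the
family ancestor) to exercise the genus- and family-level assignment
paths. `simulate_reads` builds tag+primer+template+primer'+tag'
molecules (the real *trnL* c/h primer pair by default; tags are random
8-mers at pairwise Hamming distance ≥ 3 so the perfect-match rule is
meaningful), reads both ends, applies i.i.d. substitution errors, and
records every read's (sample, template) provenance. Quality models are
constant Q35 or a two-state Q35/Q15 mix (mean 25) to exercise the Q30
filter; an N-planting fraction and a single-insertion fraction exercise
the demultiplex and merge rejection paths. All randomness flows through
one PCG64 generator, so output is byte-identical across platforms for a
fixed seed.

What the generator does **not** emulate: PCR amplification bias
(primer–template mismatch kinetics), chimeras, indel sequencing-error
processes, length variation of real amplicons, or quality decay along
the read. Passing recovery tests therefore demonstrate that the
*pipeline arithmetic* is unbiased and conservative — not that real
read proportions are quantitative diet estimates, which amplification
bias alone already prevents.

**Recovery scoring** compares recovered *Fs*/100 against the *realized*
template draw counts (from provenance), resolved to each template's
assignable taxon; because *Fs* is renormalized over assigned reads the
comparison is flagged as renormalized in the summary. With zero error
rate and divergent references, recovery is exact by construction and is
tested as such.

## Problem sizes and test design

The test and acceptance suites run entirely on synthetic data plus the
packaged study tables: end-to-end runs use 1–3 samples × 2000 read
pairs, recovery is averaged over 20 seeds in the test suite (5 in the
acceptance script), the K2P oracle uses 200 random pairs ≤ 50 bp, and
the UPGMA check uses 50 random ultrametric matrices with n ≤ 8. These
sizes were chosen so each property is exercised well past its edge
cases while the full suite stays interactive.

## Known limitations

* Merging is ungapped; an indel in the overlap rejects the pair rather
  than realigning it.
* OTU clustering is order-dependent (greedy, abundance-first) as in the
  standard tool chain; it is not a global optimum.
* The e-value calibration is ungapped and assumes uniform base
  composition.
* Rf on UPGMA trees inherits UPGMA's molecular-clock assumption; a
  rate-variable marker can fail monophyly for clock reasons alone.
* The "X spp. (except …)" residual rows list *all* finer-rank taxa of
  the lineage present in the group, which may be more verbose than
  hand-curated presentations of the same data.
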