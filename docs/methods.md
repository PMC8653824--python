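# Methods

## Scope and data model

marktax implements a single-protein marker taxonomy pipeline over seven
ordered ranks, superphylum (depth 0) through species (depth 6). Lineages
are contiguous from their shallowest assigned rank downward; a lineage
known only to order level simply lacks family/genus/species, and parsing
truncates at the first internal gap with a warning. Superphylum
participates in lineages and in shared-rank queries but is excluded from
the identity-threshold system, which spans the six ranks phylum..species.
"Candidatus" prefixes are stripped on parsing and recorded in a flag so
provisional and validated spellings compare equal; all other name
comparison is exact and case-sensitive, with no fuzzy matching. Both
GTDB-style lineage strings (`d__...;p__...;...;s__...`, the `d__` token
carried separately for round-tripping) and seven named NCBI-style rank
columns are read; when a genome carries both kinds of labels the caller
decides which table to pass — the toolkit does not arbitrate between
nomenclatures.

## Ortholog screening

`hmmsearch --domtblout` tables are parsed row-wise; multiple domain rows
for one (protein, marker) pair collapse to the row with the highest
full-sequence bit score. How multi-domain proteins should be resolved is
not fixed by any convention; max-collapse is this package's choice.
Filtering is by **full-sequence** bit score — the statistic TIGRFAM
trusted cutoffs are defined on — and cutoffs are **inclusive** (score ≥
threshold keeps the hit). Shipped defaults: TIGR03675 (aCPSF1) 580,
TIGR03256/03257/03259 (McrA/B/G) 768/516/172. Representative selection
per genome takes the highest-scoring hit, ties broken by lexicographically
smallest protein id, making the result invariant under input order.

Copy-number audits count distinct proteins per genome; summary shares use
genomes with ≥1 copy as the denominator, and per-group multi-copy shares
keep that same denominator so they read as shares of all marker-positive
genomes. Reported percentages are rounded half-up (one decimal by default,
trailing zeros trimmed), the convention that reproduces printed values
like 95.4%, 2.9% and 78%. Genome completeness is consumed as an upstream
annotation where needed, never computed.

## Percent identity

The identity of two aligned rows is `100 × matches / denominator`, where a
match requires the same residue in both rows, gaps never match, and the
ambiguity letter X matches nothing — not even X. Columns gapped in both
rows are ignored entirely. Three denominators are exposed:
`ungapped_columns` (columns where neither row is gapped; the default, the
most common convention among SIAS-style calculators), `shorter_sequence`
(residue count of the shorter row) and `alignment_length` (columns with at
least one residue). A zero denominator raises an undefined-identity error
rather than returning 0; the all-vs-all matrix records such pairs as
missing cells with a warning. Identities are computed on MSA rows as
given; no consensus sequence is built first — where an upstream workflow
speaks of consensus residues, this is an explicit interpretation choice.

## Global aligner

The built-in pairwise aligner is a standard Gotoh affine-gap global
alignment: three state matrices (substitution / gap-in-reference /
gap-in-query), a gap of length L costing `gap_open + (L−1)·gap_extend`,
defaults BLOSUM62 with open −11 and extend −1 (all configurable, including
a caller-supplied substitution table). Traceback is deterministic: on
score ties it prefers diagonal, then up, then left, applied at each step
walking from the alignment end backward. Optimality is tested against an
oracle that enumerates every gapped alignment and scores it
independently — exhaustively for all ordered sequence pairs up to length 3
over a 3-letter alphabet (1,521 pairs) plus a seeded random sample of 250
longer pairs (lengths 4–6); full enumeration over all length ≤ 6 pairs
(~600k pairs) would add hours of runtime for no additional coverage of
the recursion's cases.

## Rank normalization

Every unordered pair of reference sequences falls in the bucket of its
most specific shared rank; pairs sharing nothing at or below phylum
(different phyla, disagreement at the shallowest mutually assigned rank,
or superphylum-only agreement) are discarded and counted, so bucket sizes
plus discards always partition C(n,2). Pairs never contribute below their
lineages' assigned depth. This "partition" semantics — rather than pooling
each rank's bucket with all deeper buckets — makes the six medians
describe disjoint pair sets and yields the monotone rank structure; a
`pool_deeper` option exposes the pooled alternative for sensitivity
analysis. Thresholds are the bucket medians themselves (even-sized buckets
take the mean of the central two values), with no interpolation; a valid
table must be strictly increasing with depth, and validation names every
offending adjacent rank pair.

The shipped default table carries the published aCPSF1 medians (species
95.7, genus 87.4, family 84.9, order 84.1, class 52.9, phylum 43.2),
derived from 779 reference proteins spanning the archaeal phyla. Those
numbers require the deposited reference set and are not recomputable from
package-internal data; the package validates and uses them but re-derives
thresholds only on its own (synthetic or user-supplied) inputs.

## Classification

`best_hit` returns all references within 1e-9 of the maximal identity;
`assign_rank` returns the deepest rank whose threshold the identity meets
(inclusive — equality assigns the rank, since no strictness convention is
established for these cutoffs). The assigned lineage is the best
reference's lineage truncated at the assigned rank. Conflicting ties are
truncated further to the tied references' common lineage and flagged
`conflicted_ties`; identities below the phylum threshold yield
`unassigned_below_phylum` with an empty lineage. Multi-copy genomes are
resolved by `genome_call`: the deepest-rank copy wins, equal-depth
conflicts truncate to the common lineage and keep the flag — duplicates
are surfaced, not discarded. No alignment-coverage floor is imposed by
default (none is established for this marker); a minimum-coverage filter
can be applied upstream of the identity table. Query identities default
to the built-in aligner but any precomputed query-vs-reference identity
table is accepted, which both mirrors MSA-derived workflows and avoids
quadratic alignment cost when identities already exist.

## Profiling

The profiler consumes tabular read hits (read id, gene id, percent
identity, aligned length) from an external end-to-end mapper, or converts
a SAM file, taking identity from NM tags. Gene catalogs are deduplicated
at 100% identity and 100% coverage — byte-identical sequences collapse to
the lexicographically smallest id; no reverse-complement collapsing. Each
read contributes only its best hit (highest identity, then longest
alignment, then smallest gene id). Default filters are 95% nucleotide
identity — a within-species proxy consistent with the ~95% ANI species
boundary — and 50 bp aligned length. Relative abundance is the
assigned-read fraction per taxon at the requested rank; an optional
per-kilobase weighting is provided since no single normalization is
canonical. Rarefaction subsamples reads without replacement with a seeded
generator and reports mean and SD of distinct-taxon counts per depth;
depths beyond the read count are an error (no extrapolation).

## Synthetic data generator

The generator emulates the statistical structure rank normalization relies
on — identity strata ordered by rank — not sequence evolution. Sites are
partitioned into contiguous blocks, one per rank depth plus a
genome-private remainder. The ancestor node at depth R draws its block
uniformly over the 20 amino-acid letters and all descendants inherit it,
so two genomes whose most specific shared rank is R agree exactly on
blocks at depths ≤ R and match with probability 1/20 elsewhere:

    E[identity | diverge at R] = c_R + (1 − c_R)/20,
    c_R = (t_R/100 − 1/20) / (1 − 1/20).

Block sizes are solved from the configured targets t_R (defaults: the
shipped aCPSF1 medians), making the expectation exact up to block-boundary
rounding (< 0.2 points at the default length). The default length is 660
residues, the approximate span of an aCPSF1 protein. Optional second
within-genome copies are resampled to a configured expected identity
(default 98%), and decoys are unrelated uniform sequences. Fixture
emission writes protein FASTA, taxonomy TSV, a synthetic domtblout in
which true orthologs score `cutoff + 2 × identity-to-root` (always
passing, increasing with proximity to the root draw) and decoys score
uniformly below the cutoff, and nucleotide genes produced by fixed-codon
reverse translation (one codon per residue — nucleotide realism is
irrelevant to dedup and profiling logic). Read-hit simulation draws reads
multinomially from a taxon composition with identities `100 − |N(0, σ)|`.

What this generator deliberately omits: indels (so simulated identities
need no alignment step), rate heterogeneity across sites, empirical
substitution preferences, back-substitution along paths, and read error
models. Passing recovery tests therefore demonstrates that the bucketing,
median, threshold and best-hit machinery is correct under calibrated
conditions — not that the aCPSF1 strata themselves would be recovered from
real, indel-containing, unevenly sampled data.

## Recovery experiment

`marktax.evaluation.rank_recovery_experiment` is the package's end-to-end
self-check. Design: one phylum, two children at every internal level, six
genomes per species — 192 genomes, the smallest balanced layout that
populates all six buckets with replication — with strata
{species 96, genus 88, family 85, order 84, class 53, phylum 43}. The
marker length for this experiment is 2,000 sites, set by a power argument:
a pair identity has SD ≈ 100·sqrt(c(1−c)/L) points, and the narrowest
stratum gap (family vs. order, 1 point) must span several SDs for
rank-exact classification to be statistically identifiable at all; 660
sites (the generator's realism default) give SD ≈ 0.34 and a ~3σ gap,
2,000 sites give SD ≈ 0.20 and a ~5σ gap.

Fifty held-out queries are classified per evaluated rank against reference
sets excluding the query's clade at that rank (its genome for species, its
species for genus, and so on), using thresholds derived from the full
simulated matrix; a query counts as correct when both the assigned rank
and the truncated lineage match the design. Typical results: derived
medians within ±0.5 points of the strata and hold-out accuracy 0.94–0.98.

Known limitation: with two children per level, all of a query's rank-R
references descend from a single sibling clade, so their identities share
that clade's block draw — a cluster effect the best-hit maximum cannot
average away. Combined with median thresholds (which, by construction,
half of same-rank pairs fall below), occasional seeds dip to ~0.86–0.90
accuracy, concentrated at genus. Widening the design (more sibling clades
per level) removes the effect at the cost of the 192-genome layout.

## Numerical conventions

Percentages print with half-up rounding; identity/threshold comparisons
are inclusive; best-hit ties use an absolute 1e-9 identity tolerance;
PHYLIP export writes distance = (100 − identity)/100 with 10-character
names (generated names plus a sidecar map in relaxed mode); all random
procedures take explicit integer seeds and are reproducible bit-for-bit
for a fixed seed.
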