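# Methods

`cocult` re-implements, as library code, the computational route by which a
predatory bacterium's genome can be pulled out of a two-organism co-culture
metagenome and placed phylogenomically. This note documents the models and
procedures, the parameters that matter, what the synthetic generator does
and does not emulate, and the numerical choices made where the design was
genuinely open.

## Co-culture deconvolution

**Binning model.** A two-member culture of a high-abundance predator and a
low-abundance host separates on a read-depth vs GC-content ordination into
two clusters. Binning is a pure threshold rule, not a clustering algorithm:
predator iff `coverage > coverage_cutoff` (strict, default 180×) and
`gc_min ≤ GC ≤ gc_max` (inclusive, default 0.42–0.54). The thresholds are
explicit parameters because in practice they are read off the ordination by
eye; automating the cluster cut is deliberately out of scope. GC is
computed as (G+C)/(A+C+G+T), ignoring N.

**"Data" convention.** Per-bin shares are reported as fractions of
Σ(length × coverage) per contig — a proxy for mapped bases. Whether such a
share denominates reads, bases or mapped bases is ambiguous in routine
usage; Σ(length × coverage) is our documented choice, with a plain-bp
alternative (`bin_fractions(..., convention="bp")`).

**rRNA read screen.** Reads are assigned to reference rRNA taxa by counting
shared canonical kmers (k = 21 by default; canonical = lexicographic min of
kmer and reverse complement, so the screen is strand-invariant; k must be
odd so no kmer is its own reverse complement). A read unit is assigned to
the taxon with the largest vote if that vote reaches `min_hits` (default 5);
mates of a pair are screened independently but counted once per pair. Ties
go to the lexicographically smallest (taxon, gene) and are recorded. This
is an exact-kmer classifier, not a profile-HMM/placement method: on data
whose references share no kmers with the genomic background it is exact,
and that is the regime the generator produces. The engine packs bases two
bits each into uint64 codes and tests membership with vectorised sorted-
array searches, so ~200k reads screen in ~20 s on one CPU.

**Circularity.** A contig assembled from a circular replicon carries its
junction as a terminal repeat: its 5′ and 3′ ends share a (k−1)-mer
(k = 51 → 50 bp overlaps). The end graph joins any two contig ends whose
terminal (k−1)-mers match in an orientation-consistent way (suffix→prefix
for same-strand joins; reverse-complement-aware for 3′–3′ and 5′–5′
joins). A contig is called circular iff its two ends join *each other and
no other end* — the unambiguity rule — and, when reads are supplied, at
least `support_cutoff` (default 15) reads contain the junction-spanning
2(k−1)-mer on either strand. This is a contig-level re-statement of a
read-graph traversal: the published criterion is checkable from contig
ends alone, and the read-support layer maps the original "coverage cutoff
of 15" onto junction-spanning read count (an interpretation, documented as
such; whether the original tool meant kmer coverage in the read graph is
not stated). Contigs shorter than k are skipped with a warning.

**Marker QC.** Completeness and contamination from a single-copy marker
table (counts `c_m` over a set of M markers, default M = 104):

    completeness  = 100 · |{m : c_m ≥ 1}| / M
    contamination = 100 · Σ max(c_m − 1, 0) / Σ c_m      (default)
                  = 100 · Σ max(c_m − 1, 0) / M          (alternative)

Both contamination denominators circulate among binning QC tools; with
104/104 markers found and one duplicate they give 1/105 = 0.95% and
1/104 = 0.96% respectively. The detected-copies convention is the default
(it reproduces the commonly printed rounding for that table) and every
report carries its convention in the output metadata; the discrepancy
between the two is documented rather than resolved. Marker detection is
exact 60-mer tag matching on both strands — the contract here is the
counting arithmetic; homology search belongs to external tools.

## Phylogenomic marker curation

Four steps over a presence/copy-number matrix of gene families × trusted
genomes, with all thresholds strict `>` (boundary cases fall on the
excluded side, and are unit-tested there):

1. **Prevalence** — keep families present *exactly once* in >90% of the
   trusted genomes. A family single-copy in exactly 90% is excluded.
2. **Redundancy collapse** — the same protein family may be annotated by
   two databases (source A, Pfam-like; source B, TIGRFAM-like). An (A, B)
   pair is redundant when both hit an identical, non-empty gene-id set in
   >90% of the trusted genomes; the A-family is dropped, preferring B.
   "Matched the same genes" is operationalised as per-genome gene-id set
   equality; partial-overlap comparators are not the default because no
   published definition of partial overlap exists for this step. Only A–B
   comparisons are made (A–A/B–B redundancy is undefined in the source
   procedure), and each A collapses onto at most its first matching B in
   sorted order.
3. **Congruence** — for each genome with ≥2 copies of a family, find the
   MRCA of the copies in the family's gene tree; the genome is congruent
   iff every leaf under that MRCA belongs to a genome of the same species
   (a single conspecific clade). Single-copy genomes are vacuously
   congruent. Gene trees are inputs (generated or user-supplied, read as
   rooted as given); a multi-copy genome absent from its family's tree is
   conservatively counted divergent, with a warning.
4. **Divergence filter** — drop families divergent in >1% of *all* trusted
   genomes. The denominator is the full trusted set, not the genomes
   carrying the family.

The audit trail records the initial (prevalence-passing) set, the collapsed
pairs, the candidate set, the divergence-removed set and the retained set;
retained = candidates − removed by construction, and the outcome is
invariant to family input order.

## Tree inference

**Supermatrix.** Per-family alignment blocks are concatenated in a fixed
family order; a genome absent from a block contributes an all-gap segment.
Block boundaries are exported 1-based inclusive (`partitions.tsv`).

**LogDet (paralinear) distance.** For a pair of aligned rows, sites where
either has a gap or N are excluded (pairwise deletion; Lane-mask-style
column filters can be applied upstream as a column subset). With F the 4×4
joint relative-frequency matrix over usable sites and r, c its marginals:

    d = −¼ · [ ln det F − ½ · Σᵢ ln(rᵢ cᵢ) ]

Rows/columns for bases absent from *both* sequences are dropped before the
determinant, which keeps identical sequences at distance exactly 0
whatever their composition; a base present in only one sequence, zero
usable sites, or det F ≤ 0 raise a saturation error. In the
equal-frequency, low-divergence limit LogDet approaches the Jukes–Cantor
distance −(3/4)·ln(1 − 4p/3); the suite checks agreement within 5%
relative at p ≤ 0.1.

**Neighbour joining.** Saitou–Nei agglomeration: join the pair minimising
Q(i,j) = (n−2)·d(i,j) − Rᵢ − Rⱼ; branch lengths
ℓᵢ = d(i,j)/2 + (Rᵢ − Rⱼ)/(2(n−2)); update
d(u,k) = [d(i,k) + d(j,k) − d(i,j)]/2. NJ is exact on additive matrices
(verified exhaustively over all unrooted topologies at 4 and 5 taxa and on
random 8-taxon trees). Numerical choices: Q ties (within 1e−12) are broken
towards the lexicographically smallest cluster pair, where a cluster is
named by its smallest leaf — this makes output deterministic; negative
branch lengths are clamped to 0 with the deficit moved to the sister edge,
preserving the pair's summed length.

**Bootstrap.** Columns are resampled with replacement per replicate; an NJ
tree is inferred per replicate; each internal edge of the tree from the
*original* matrix is annotated with the percentage of replicates containing
the same (unrooted) bipartition, rounded to an integer. A replicate whose
resampled matrix leaves some pair without usable sites (or saturated) is
skipped and logged; the denominator stays `n_reps` so skipping can only
lower support, never inflate it. Default 100 replicates.

The in-repo inference engine is deliberately the NJ+LogDet path;
maximum-likelihood inference is delegated to external tools (the
supermatrix export exists for that purpose) and the package does not claim
to reproduce ML topologies. It is applied here to nucleotide supermatrices.

## Synthetic data: what it emulates, and what it does not

The generator is first-class, tested code; its defaults *are* the study
conditions the pipeline is validated under.

**Co-culture** (`CocultureParams`): predator chromosome at GC 0.514,
200 kbp (a scaled stand-in for the real 2.91 Mbp), pre-fragmented into 26
contigs; two circular plasmids of 14.4 and 10 kbp (stand-ins for ~72 and
~50 kbp) at chromosome-like coverage, linearised with a 50 bp terminal
overlap; a host fraction at GC 0.61 and 30× sized (119 kbp) so the
predator holds ~94% of Σ(length × coverage) in closed form, split into 85
contigs so the assembly totals 113; predator coverage 250× (comfortably
above the 180× cutoff, >3× separation from the host). Scaling down keeps
the full pipeline in tens of seconds while leaving every threshold,
fraction and count at its real value; all paper-scale constants remain
configurable. Background sequence is i.i.d. per base with
P(G) = P(C) = GC/2, so expected GC is analytic (sd ≈ 0.1 percentage points
at 200 kbp). Reads are error-free 2×300 bp pairs with uniform fragment
starts (insert 700 bp; wrap-around sampling on circular plasmids, which is
what makes junction-spanning support reads exist); the coverage table is
derived from the reads actually sampled. 104 unique 60-mer marker tags are
planted into the chromosome, one of them twice (→ completeness 100%,
contamination 1/105); generation asserts each tag occurs exactly its
planted number of times. rRNA reference sequences (predator 16S, host
18S, chloroplast 16S, mitochondrial rRNA) are generated and fragments are
planted into a recorded subset of reads — 333 predator-16S, 16
chloroplast, 3 mitochondrial by default, with the 18S reference left at
zero planted reads as a specificity control.

Not emulated: sequencing error, indels, repeats, strain microheterogeneity,
chimeric contigs, GC-coverage bias, and the assembly step itself (contigs
are emitted pre-fragmented; assembly is out of scope). Passing tests
therefore show the *rules* are implemented exactly and recover planted
structure under clean separation; they do not show robustness to assembler
artefacts or borderline clusters on real data.

**Marker scenario** (`MarkerScenarioParams`): 50 trusted genomes in 25
two-genome species on a random species tree. 200 families across the two
sources; 188 pass prevalence by construction, 10 planted redundant (A, B)
pairs collapse to leave 178 candidates; 69 candidates carry one genome
with a duplicated copy grafted into a *different* species' subtree
(divergent fraction 1/50 = 2% > 1%), a further 20 carry a congruent
duplication (sister copies, fraction 0), and the prevalence-failing
families sit exactly at the 90% boundary to pin the strict inequality.
Redundant pairs share identical gene ids in ⌊0.9n⌋+1 genomes — the
smallest count strictly above the 90% threshold at any n. Alignment blocks
(100 columns per family) evolve by site-independent substitution down the
genome tree (per-edge substitution probability ¾(1−e^(−4t/3)), i.e. a
Jukes–Cantor edge), giving conspecific cherries ~2% divergence and clear
between-species signal. Not emulated: rate heterogeneity, indels/real
gaps, horizontal transfer beyond the planted grafts, incomplete lineage
sorting.

Determinism: identical parameters + seed give byte-identical outputs; the
pipeline fans one run seed out to fixed per-stage child seeds
(`numpy.random.SeedSequence.spawn`) so stages re-run independently.

## Degenerate inputs and edge behaviour

Zero coverage → zero reads and an all-zero coverage table; empty marker
table, empty presence matrix, <3 taxa for NJ, <4 taxa or 0 replicates for
bootstrap, and unequal aligned lengths are errors. A contig missing from
the coverage table names itself in the error. A contig whose ends join
each other but also something else is `ambiguous-join`; with reads
supplied, a self-join below the support cutoff is `insufficient-support`.

## Problem sizes used in validation

The test suite and acceptance script run the generators at their defaults
(200 kbp predator, ~99k read pairs, 50 genomes × 200 families) plus
scaled-down variants (30 kbp / 20 genomes) for multi-seed sweeps: 20 seeds
for binning truth recovery and selection truth recovery, 50 random
8-taxon additive matrices for NJ, 20 seeds for bootstrap support of a
planted split. The full default pipeline, generation through the
100-replicate bootstrapped tree, completes in roughly a minute on one CPU.

## Known limitations

* The kmer screen and tag-based marker counting are exact-match methods;
  they stand in for HMM-based homology search and will not find diverged
  homologues on real data.
* Redundancy collapse implements only the stated A→B preference; chained
  or many-to-many redundancies collapse pairwise in sorted order.
* LogDet pairwise deletion can use different site sets per pair, so the
  distance matrix is not guaranteed additive (as with any pairwise-deletion
  distance); NJ consumes it regardless.
* The circularity check cannot distinguish a true circular replicon from a
  linear contig that happens to carry identical 50-mer termini; on real
  data the read-support layer is the guard.
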