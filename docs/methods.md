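# Methods

This note documents the models, estimators and design choices behind
chromoforge, module by module, including what the synthetic data does and
does not emulate.

## Synthetic study conditions (`synth`)

The simulator's defaults define the study the test suite and acceptance
script run: 3 chromosomes of 2 Mb, 10 scaffolds per chromosome, 900 SNP
markers, 200 progeny. Physical scale is deliberately desk-size; what
two-point anchoring actually senses is *genetic* distance, so the map
density default is `cm_per_mb = 50`, giving each 2 Mb chromosome ≈ 100 cM —
a realistic genetic length for a plant chromosome. Equivalently, the
simulation compresses physical coordinates while keeping the recombination
landscape full-size.

**Genome.** Chromosome sequences are i.i.d. uniform A/C/G/T. Scaffold
lengths follow a log-normal spread (σ = 0.4) normalized to the chromosome
length minus fixed 100 bp inter-scaffold gaps of true (unassembled)
sequence; orientations are random signs; marker positions are uniform over
scaffold-covered sequence, distinct and sorted. A scaffold that tiles a
whole chromosome is reported as `+`, since its sign is a pure gauge choice.

**Cross.** The population is an outcross (CP) progeny. Each marker is
assigned one of three segregation classes — lm×ll, nn×np (testcross in one
parent, 1:1) and hk×hk (both parents heterozygous, 1:2:1) — with default
proportions 40/40/20%, and an independent random linkage phase per
informative parent. Meioses follow the Haldane model (no crossover
interference): a parental inheritance indicator is a Markov chain along each
chromosome whose switch probability between markers d cM apart is
r = (1 − e^(−2d/100))/2. Both parents recombine independently on the same
map (no sex-specific map lengths).

**GBS degradation.** Per-call depth is Poisson(mean_depth); genotype errors
are symmetric category flips at rate `genotype_error_rate` (phase errors of
hk×hk heterozygotes are subsumed by the flip model); calls are erased at
rate `missing_rate`. Degradation is a pure function — the clean matrix
remains available as truth. With both rates at zero the call matrix is
unchanged (depths are still redrawn, since the depth model is part of the
degradation).

**Chimeras and mate pairs.** A chimeric contig concatenates two whole
scaffolds; the junction coordinate is recorded. Mate pairs (100 bp reads,
Normal(insert_mean, insert_sd) inserts truncated to the segment) are sampled
only from contiguous true sequence, so junctions receive zero spanning pairs
by construction. Read-level base errors, FASTQ output and long-read
simulation are deliberately out of scope: the screen consumes alignments,
not reads.

**What passing tests do and do not show.** The simulator has uniform marker
density, no segregation-distortion hotspots, no centromeric recombination
suppression, no repeat-induced mis-mapping and no linked-error structure.
Recovery rates measured here are therefore upper bounds for real data; the
known hard case — ordering scaffolds inside low-recombination pericentromeric
regions, where genotyping error mimics recombination — is exactly the regime
the simulator does not model.

## Misassembly screen (`screen`)

Spanning coverage at position p counts proper pairs whose left read ends at
or before p and whose right read starts after p; it is computed with a
difference array in O(pairs + length). Breakpoints are maximal runs with
coverage below `min_span` (default 1, i.e. literally *no* spanning pair),
clipped to the interior `[edge_exclusion, L − edge_exclusion)`; runs confined
to the edge zones are not called, because contig ends cannot be spanned.
`edge_exclusion` should be at least the largest library insert (the pipeline
uses mean + 3 SD). Each run is reported once at its midpoint; multiple
breakpoints per contig are allowed. Splitting cuts at breakpoint positions,
drops fragments below 1000 bp and renames fragments `<id>_1`, `<id>_2`, …

The organelle screen aggregates BLAST outfmt-6 HSPs per (contig, subject):
query coverage is the merged non-overlapping HSP footprint over the contig
length, identity the alignment-length-weighted mean, E-value the minimum.
The chloroplast rule (identity ≥ 98 and coverage ≥ 80) and mitochondrion
rule (E < 1e-40) remove a contig on any qualifying hit.

Only the *absence of concordant* pairs is used as evidence; discordant-pair
counting is not implemented.

## Marker QC (`qc`)

Inequalities are strict exactly as the defaults read: depth < 10 masks,
missing > 50% drops, MAF must be > 0.01, segregation P must be > 1e-6
(Pearson χ², 1 df for 1:1, 2 df for 1:2:1, no continuity correction). The
cascade order — biallelic → depth mask → missingness → MAF → χ² — is part of
the contract because depth masking changes missingness: the filters do not
commute. MAF expands genotypes to allele counts (for testcross markers the
segregating parent's alleles as seen in progeny, for hk×hk the h/k tally);
it is computed after depth masking. A VCF without per-sample DP loads, but
depth masking then raises instead of silently passing everything.

## Two-point linkage (`linkage`)

For a marker pair, a parent contributes linkage information only if it is
heterozygous at both markers. Genotype classes are coded by minor-allele
count, so the joint class distribution is a polynomial in r:
P(class) = Σ_k K[class, k] · r^k (1−r)^(G−k), where G ∈ {1, 2} is the number
of doubly-heterozygous parents and the coefficient matrix K is derived once
per (type pair, phase combination) by enumerating gamete configurations.

* Same-parent testcross pairs: r̂ is the recombinant count under the better
  of the two phases, capped at 0.5 (closed form; the EM reduces to it
  exactly on these unambiguous tables, which is tested).
* Pairs involving hk×hk: EM over the class counts (≤ 100 iterations,
  Δr < 1e-6, start 0.25), run for every phase combination of the informative
  parents; the phase with the highest log-likelihood wins, and likelihood
  ties (within a relative tolerance — mirrored phases produce exactly
  mirrored likelihood curves) resolve to the smaller r̂.
* lm×ll × nn×np pairs carry no two-point information; they are flagged
  unusable with `n_inf = 0` rather than raising. `n_inf` counts informative
  progeny (jointly observed, informative type pair).

LOD = (ll(r̂) − ll(0.5))/ln 10, clipped at 0; at r = 0.5 gametes are
independent so the phase does not matter. Missing data are handled by
pairwise deletion. The full matrix is computed block-wise per type pair with
vectorized class counting (indicator-matrix products), so the 900-marker
default takes seconds.

Linkage groups are single-linkage connected components of the graph with
edges rf ≤ `rf_max` (0.35) and LOD ≥ `lod_min` (5) — conventional grouping
thresholds, CLI-exposed. Groups are labeled by decreasing size with ties on
the smallest member id, making labels input-order invariant. The scaffold
consistency check reports any scaffold whose markers (counting only groups
of ≥ 2 markers) span two or more linkage groups.

## Anchoring (`anchoring`)

Scaffold divergence D(s, t) is the unweighted mean of usable rf entries over
the two scaffolds' marker sets; pairs with no usable entry have undefined D.
Block-pair distance for the agglomerative merge is the mean over *defined*
cross-block divergences and +∞ only when none is defined — treating any
undefined entry as +∞ would make an average with one missing pair infinite
and forbid merges backed by plenty of other evidence. Disconnected groups
yield multiple blocks, returned largest first with a warning.

Each merge joins the two closest blocks at one of the four end-to-end
junctions (A·B, A·B̃, Ã·B, B·A), scored by the mean rf between the facing
`k_terminal` (default 3) markers; a junction with no usable marker pair
scores the maximum 0.5 so uninformative junctions are never preferred. Ties
in block distance break on the lexicographically smallest scaffold-id pair,
making the whole construction deterministic and input-order invariant.

One optimization "round" is defined here as steepest descent to a local
fixed point: repeatedly evaluate all single-scaffold flips, adjacent swaps
and single-scaffold relocations and apply the best cost-reducing move until
none improves. The cost never increases, and on groups of ≤ 5 scaffolds the
result matches exhaustive search over all n!·2ⁿ signed orders (tested on
random instances).

Whole-chromosome reflection is unresolvable from rf alone; layouts are
canonicalized with the lexicographically smaller end scaffold leftmost, and
all truth comparisons score up to per-chromosome reflection. Scaffolds with
fewer than two distinct marker positions have no internal direction: they
are emitted as `+` with `orientation_known = False` and excluded from
orientation accuracy.

## Pseudomolecules and statistics (`pseudomolecule`)

AGP v2.0 is the interchange format: 1-based inclusive in files, converted
from the 0-based half-open internal convention at the boundary. Anchored
scaffolds alternate with N gap records (default 100 N; gap type "scaffold",
linkage "yes", evidence "map" — the inter-scaffold gap size is a
convention, configurable). Unanchored scaffolds are emitted as their own
single-record objects. Chromosomes are named `chr1…chrN` by decreasing
anchored length. N50 is the length at which the cumulative sorted-descending
length first reaches half the total; unknown sites count N/n; anchored % is
anchored scaffold length over total assembly length. Density tracks tile
each chromosome with non-overlapping windows (default 400 kb) from 0, count
features by start position and include the final partial window.

## Liftover (`liftover`)

Probes are exons extended by `flank` (default 20) bp on both sides, clipped
at sequence bounds with the actual flank recorded so coordinates de-flank
correctly. Placement requires exact full-length occurrence, found on both
strands by substring scanning. A gene transfers iff every exon probe hits
and exactly one consistent placement exists: one target sequence, one
strand, exons colinear in gene order (reversed on the minus strand),
non-overlapping, positive inter-exon spacing, and intron lengths inflated at
most 10× (configurable) relative to the source — the inflation bound rejects
spurious colinear hits scattered across a chromosome. Multiple consistent
placements fail as `multi-hit-ambiguous` rather than picking one; an
aligner-based rescue of failed genes is intentionally out of scope.

## Pipeline (`pipeline`, `cli`)

Stages run in fixed order (simulate → screen → qc → linkage → anchor →
build → liftover) from one TOML config whose unknown sections/keys are
rejected. All thresholds appear as named defaults (`min_depth=10`,
`max_missing=0.5`, `min_maf=0.01`, `seg_p=1e-6`, `min_contig=1000`,
`flank=20`, chloroplast 98/80, mitochondrion 1e-40). The master seed drives
every stage through independent seed streams; no artifact embeds a
timestamp, so reruns are byte-identical and the run report carries a SHA-256
manifest of every file. Disabling QC while linkage is enabled records a
warning (linkage then runs on raw genotypes); a stage whose prerequisite is
disabled aborts with a typed error naming the stage.

## Numerical conventions and degenerate inputs

Coordinates are 0-based half-open internally, converted at file boundaries
(VCF/GFF3/AGP are 1-based inclusive). rf is capped at 0.5 and LOD at ≥ 0.
EM probabilities are clipped away from 0/1 (1e-9) to keep log-likelihoods
finite. Empty inputs return empty/zero results (empty genotype matrix, empty
assembly stats, contig with no pairs → all-zero profile); a marker with no
observed calls is dropped with an explicit "no data" reason rather than a
NaN propagating.

## Problem sizes used in the checks

The acceptance script and heavier tests use the default study (3 × 2 Mb,
900 markers, 200 progeny), a 100-contig misassembly screen with 20 chimeras
at 20× (insert 5 ± 0.5 kb), 200 random ordering instances of ≤ 5 scaffolds
compared against exhaustive search, 100 EM-bias replicates at n = 400 per
rf ∈ {0.05, 0.2, 0.4}, 50 random 200 × 200 QC matrices against loop oracles,
and 100 random ≤ 100 kb targets for probe-placement oracle equivalence.
These sizes keep the whole suite comfortably within a coffee break on one
CPU while leaving every estimator's sampling error well inside the asserted
margins.

## Known limitations

* Two-point information only: no multipoint map, no per-group marker
  ordering beyond scaffold-internal physical order.
* Grouping thresholds are conventional defaults, not a re-derivation of any
  specific mapping software's grouping ladder.
* The misassembly screen requires the interior of both chimera flanks to
  exceed the edge exclusion; junctions closer than one insert length to a
  contig end are undetectable by construction.
* MAF for an outcross is a pragmatic definition (allele counts within the
  segregating configuration); other conventions exist.
* The liftover is exact-match only; diverged assemblies need an aligner,
  which this package deliberately does not wrap.
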