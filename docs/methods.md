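# Methods

This note documents the models, algorithms and numerical conventions behind
mapforge, the choices made where the design was genuinely open, and what the
synthetic-data tests do and do not demonstrate about real data.

## RIL panel simulator (`rilsim`)

**Meiosis.** Crossovers are modelled as a no-interference Poisson process at
one expected crossover per 100 cM. At the marker level this process is
simulated exactly as a Markov chain on transmitted phase: between adjacent
markers separated by d cM the phase switches with the Haldane probability
r = (1 − exp(−2d/100))/2, independently across intervals, with a fair start
phase. This is distributionally identical (restricted to marker loci) to
drawing a Poisson crossover count with uniform breakpoints, and it
vectorises over lines. No interference is assumed because it is the simplest
process whose two-point expectations are closed-form — which the test suite
exploits — not because real wheat meiosis lacks interference.

**Inbreeding.** Lines descend from a single F1 through
`selfing_generation − 1` rounds of selfing, simulated generation by
generation (both gametes drawn from the same individual). Residual
heterozygosity therefore decays as (1/2)^g and differs between F2:6 and
F2:8 panels, as in real RIL series. The `residual_het_rate` parameter
controls how heterozygous genotypes are *reported*: `None` keeps the natural
selfing heterozygosity; a float p retains each het call as `H` with
probability p and resolves the rest to a random homozygote (p = 0 emulates
an assay that never reports hets). Observed residual heterozygosity per
population is not published for the emulated study, so this is exposed as a
free parameter defaulting to the natural process.

**Noise model.** Genotyping errors are symmetric allele flips applied to
homozygous calls after inheritance; missingness is applied last. The order
matters only at the second decimal of the rates and is fixed for
reproducibility. Defaults (5% missing, 0.5% error) are typical array-QC
residuals; population sizes default to the 176–275-line range of the
emulated four-population panel and marker sharing to an independent 40%
Bernoulli subsample per population, which reproduces the observed pattern
that roughly half of all markers are private to one map.

**Multi-locus assays and translocations.** A duplicated assay is emitted as
one genotype column (from its first locus) plus a registry of all true loci
— one array probe hybridising at several genome positions yields a single
call vector. Truth-side duplication analyses therefore run on the registry.
A `TranslocationSpec` relocates a cM segment from one chromosome to another
before simulation; `translocate_loci` applies the same rule to a locus
table so duplication evidence reflects the rearranged genome.

**What the simulator does not emulate.** Segregation distortion, crossover
interference, batch effects, allele-specific error rates, and cluster-calling
artefacts of real array genotyping. Passing recovery tests on this generator
shows the pipeline's algorithms are correct under their stated model, not
that real wheat maps of this density are always recovered at the same
accuracy.

## QC (`qc`)

Rules applied in order: (i) H → missing; (ii) drop markers with missing
fraction strictly > `max_missing_rate` (default 0.10); (iii) drop markers
whose allele-A frequency over non-missing calls falls outside the inclusive
band [0.3, 0.7]. Frequency is computed after H-masking. The boundary
conventions (strict "over", inclusive band) are a literal reading of the
usual phrasing and are recorded in every report so that retained counts are
exactly reproducible. QC is idempotent and monotone in the missing
threshold; both properties are tested.

## Two-point engine (`linkage`)

For a marker pair, lines homozygous and non-missing at both markers are
informative (n); discordant lines are recombinant (k). The observed RIL
fraction R = k/n (capped at 0.5) is corrected to the meiotic fraction by the
Haldane–Waddington relation r = R/(2(1 − R)), the exact inverse of
R = 2r/(1 + 2r) for fully selfed RILs. F6/F8 panels are treated as fully
inbred: the generation-specific correction changes distances by under 1%
at these generations. The LOD is the binomial log10 likelihood ratio at the
MLE, with R floored at 1/(2n) when k = 0 so that zero-recombinant pairs
score finite, large LODs rather than infinities. Map distances use Kosambi
by default (the common default of single-population mapping tools; the
emulated study does not state its function) with Haldane switchable; r ≥ 0.5
is capped at a configurable maximum distance (default 100 cM) with a
warning. All-pairs statistics are computed by two matrix products over a
±1/0 encoding.

## Single-map construction (`map_builder`)

**Binning** uses observed k = 0 (not a recombination-fraction threshold),
with single-linkage closure because missing data makes the zero-recombinant
relation non-transitive. Frame markers are elected by minimum missing rate,
ties broken by a seeded random draw.

**Grouping** is single-linkage transitive closure over frame pairs with
LOD ≥ 7. Node-based grouping tests (as in some established tools) differ in
edge cases; single-linkage is used because only the threshold is specified
in the emulated workflow, and is documented as such.

**Ordering** minimises SARF. The published tools' ordering algorithms are
black boxes, so the implementation is a standard seriation stack — greedy
nearest-neighbour chain, 2-opt segment reversal, exhaustive window-4 ripple,
iterated to a fixed point — whose correctness is bounded at small scale by
an exhaustive-permutation oracle (exact minimum on all tested groups of
≤ 8 markers). Orientation is canonicalised (first frame name sorts before
the last) because within-map orientation is arbitrary.

**Assembly** accumulates Kosambi distances between adjacent frames from 0,
places bin members at their frame's position, and assigns groups to
chromosomes by majority vote over an optional marker → chromosome anchor
table (ties left unassigned with a warning).

## Consensus merging (`consensus`)

Every linkage group of every input map contributes one directed path with
weight 1.0. Before the union, paths are co-oriented: a path whose shared
markers run counter to the already-merged frame (negative position
covariance) is flipped — real workflows orient groups by physical anchors;
here orientation is recovered from the maps themselves.

Cycles in the merged graph are ordering conflicts. They are resolved by
repeatedly deleting, inside a strongly connected component, the edge with
minimal support (ties: larger distance, then lexicographic), logged for
audit. Deleting edges rather than vertices keeps every marker mapped, which
matches how the published consensus retains all input markers; the
alternative (vertex deletion, as in one published merger) discards markers.

Linearisation realises a "mean distance approximation": consensus order is
a topological sort with ties broken by mean anchored source position (then
name, for determinism); each path is anchored by shifting it so its first
marker shared with the already-anchored set matches that marker's current
mean position; a marker's raw position is the mean of its anchored source
positions; and raw positions are projected to monotonicity along the
consensus order by pool-adjacent-violators (weights = number of source
maps). This realisation is exact for consistent inputs: the consensus of
one map — or of n copies of one map — reproduces that map to numerical
precision (tested at 1e-9), and every source adjacency not deleted by
conflict resolution is respected as a precedence.

Rescaling divides consensus positions by the mean over source paths of the
OLS slope of consensus-on-source positions over shared markers (equal
weights), correcting the distance inflation characteristic of DAG merging;
degenerate regressions (< 2 shared markers or zero variance) are skipped
with a warning. Markers with identical rescaled positions (equality after
rounding to 1e-6 cM; PAV pooling makes ties exact) share a recombinant bin.

## Summaries, validation, duplication, anchoring

Aggregation of per-chromosome (markers, bins, length) rows to genome,
homoeologous-group and total rows recomputes densities as markers/length
with half-up rounding to 2 decimals (coverage percentages: 1 decimal),
matching how such tables are conventionally printed. Chromosome names are
parsed as <group digit><genome letter> with optional arm suffix; other
nomenclatures are supplied as an explicit mapping.

Reference classification labels each query marker consistent (same
chromosome in both maps), inconsistent (different chromosome) or new (query
only); inconsistency is defined at whole-chromosome granularity, and
Spearman rho per chromosome uses consistent markers only. Interval profiles
use half-open 5-cM windows anchored at 0; gaps are adjacent *distinct*
positions differing by more than 10 cM; the marker-vs-bin window correlation
is Pearson's r. Correlations from fewer than 3 points are reported missing
(NaN), never extrapolated.

Multi-locus analysis expands m loci of one assay into m(m−1)/2 unordered
pairs, classifies each pair as homoeologous (same group, different genome),
intra-genomic (same genome, different group) or inter-genomic (both
differ), excludes same-chromosome pairs into a separate tally, and computes
homoeolog collinearity as Spearman rho of paired positions. All loci of an
assay are treated symmetrically; which locus carries the "true" signal is
not modelled.

BLAST anchoring consumes tabular (outfmt 6) hits; the E-value threshold is
strict (< 1e-10 passes) and best hits are chosen by minimum E-value, ties by
higher identity then lexicographic subject, making the choice stable under
row reordering. EST deduplication keeps one EST per (EST, chromosome, bin);
an EST bin on a different chromosome than the SNP's map position is logged
as a cross-assignment and excluded from coverage.

## Problem sizes and determinism

The simulation-based tests use 3 chromosomes × 60 markers with four
populations of 176–275 lines (the published panel's size range) and 40%
per-population marker sampling; the calibration test uses 10,000 lines at
four recombination fractions; the seriation oracle covers 50 random groups
of ≤ 8 markers. These sizes make every statistical check well-powered while
the whole suite runs in seconds. All randomness flows through explicit
integer seeds (numpy Generator); identical seeds reproduce byte-identical
genotype matrices and consensus TSVs.

## Known limitations

- Two-point distances only; no multipoint/HMM re-estimation or error
  imputation, so very tight marker pairs with genotyping errors can inflate
  local distances (partly compensated by consensus rescaling).
- Single-linkage grouping can chain across a moderate gap that a node-based
  test would split, and vice versa.
- The seriation is a local-search heuristic; global optimality is only
  guaranteed where the exhaustive oracle applies (small groups), though the
  end-to-end recovery tests bound its practical behaviour.
- Consensus bin membership depends on exact position ties; maps merged from
  very noisy inputs produce fewer ties and hence more singleton bins than a
  likelihood-based binning would.
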