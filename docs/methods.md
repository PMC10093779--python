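# Methods

## Data model and coordinate system

All stages share one binned genome: an ordered set of chromosomes tiled by
fixed-size bins (0-based, half-open bp coordinates; the terminal bin of a
chromosome may be shorter). Copy-number states are ordered pairs
(cnA, cnB) of non-negative integers, where cnB always refers to the same
phased haplotype in every bin of every cell. All genome fractions reported
anywhere are length-weighted.

The default synthetic genome is 22 autosomes with real autosome length
proportions scaled to 550 Mb total, analysed in 5 Mb bins (~110 bins).
Scaled lengths are rounded to 2.5 Mb so that terminal bins never degenerate
into slivers: a 10 kb remainder bin carries ~2 reads at 0.02X and its
modal state across cells is essentially random, which showed up as phantom
events on otherwise clean consensus profiles. Full hg19 autosome lengths
are available through the config (`genome.use_hg19`) and are used by the
tree-recovery experiments, where event interactions must be rare.

## Synthetic-data generator

`simulate_clonal_truth` draws a rooted clone tree: truncal events on the
edge from the diploid root to the founder clone, and `n_private_events`
per later edge, with each later clone attached to a uniformly random
existing clone (or in a chain/star when requested). An event picks a
chromosome uniformly, then a uniformly random sub-interval of at least
`min_event_bins` bins, a haplotype uniformly, and is a loss with
probability `deletion_bias` (default 0.6, giving the deletion-dominated
karyotypes the downstream metrics are designed for). Events that would
drive a haplotype below zero *or regain a haplotype at zero* are resampled
and counted; permitting regains would break the LOH-irreversibility
invariant every other stage relies on, so both directions are treated
alike. A whole-genome doubling is placed
on the truncal edge with probability `p_wgd`, before the truncal interval
events (an early doubling; the order is a convention, exposed nowhere
because no downstream quantity depends on it).

`simulate_cells` emulates sparse droplet sequencing. Each cell is normal
diploid with probability `normal_fraction` (default 0.1), a noisy cell
with probability `noise_cell_fraction` (a clone profile with each bin
resampled from {0..4}² with probability 0.3 — the kind of cell a quality
filter should discard), otherwise a tumor cell drawn by clone proportions.
The cell's read budget is `coverage × genome_bp / read_length` with
coverage Gamma-distributed around 0.02X (CV 0.25, spanning roughly the
0.01–0.05X range); bin counts are Poisson with mean proportional to
bin length × total copy number (negative binomial with configurable
overdispersion as an option — Poisson keeps closed-form means for tests).
SNP-overlapping reads are a binomial thinning at rate
`snp_density × read_length` (default density 1/1500 bp, the human
heterozygous-SNP scale), and B-haplotype counts are binomial with success
probability cnB/(cnA+cnB), 0.5 in empty bins.

What the generator does **not** emulate: GC and mappability bias,
replication timing, doublets, barcode errors, phasing switch errors, and
segmentation noise correlated across neighbouring bins. Tests passing on
this generator therefore demonstrate the correctness and statistical
behaviour of the downstream algorithms under idealised sparse counts, not
robustness to the systematic artefacts of real libraries.

## Per-cell calling

RDR is (cell bin proportion)/(reference proportion); the reference is the
pooled matched-normal cells when present, else the pooled cohort. By
construction the reference-weighted mean of RDR is 1, so a candidate
genome ploidy γ maps directly to a candidate scale s = γ. Each grid
anchor (default grid 1.5, 2, …, 4) is refined within ±0.25 in steps of
0.025: real tumor ploidies sit between grid points, and an unrefined
anchor can be out-fit by its own genome-doubled echo at twice the scale
(the doubled solution matches every BAF split exactly and loses only on
the RDR residual, so the correctly-scaled solution must actually be
representable to win). Near-ties in the objective break toward the lowest
implied ploidy — the diploid interpretation of a perfectly balanced
genome. The per-bin objective weighs squared RDR residual to the nearest
integer total against the squared BAF deviation of that total's best
split, weighted by SNP support; with no BAF anywhere the objective falls
back to RDR only (logged).

Totals are `round(s·RDR)` clipped to [0, max_cn = 8]; the allelic split
minimises |cnB/t − BAF| with ties toward cnA ≥ cnB, and missing BAF gives
the most balanced split. Calling is strictly per-cell; joint structure is
recovered by the clone step. At 0.05X-equivalent support this reproduces
≥99% of bins in ≥95% of cells on synthetic truth; at 0.02X, per-bin
accuracy (~99%) is ample for clone assignment but individual cells do
carry miscalled bins — which is exactly why consensus profiles, not
single cells, feed the phylogeny.

## Clone identification

The cell–cell distance is the length-weighted fraction of bins whose
ordered states differ. Average-linkage agglomerative clustering is cut at
`error_rate` = 0.12 — the expected per-cell call error at this coverage;
the choice of clustering algorithm behind that tolerance is this
package's own (the tolerance, not the algorithm, is the anchored
constant). Clusters smaller than `min_clone_size` (default max(5, 1% of
cells)) dissolve into a NOISY pool. Consensus is the per-bin modal state,
ties resolved toward the medoid cell's state (then the smallest state for
full determinism). Because an average-linkage cluster can contain members
farther than the cut from the consensus, a post-pass demotes such members
to NOISY so the advertised invariant — every assigned cell within
`error_rate` of its consensus — holds exactly; one reassignment pass then
rescues any NOISY cell within the tolerance of some consensus. Processing
is order-independent (cells are sorted by id internally).

## Metrics

WGD is decided at the clone level — true when more than half the genome
(length-weighted) has both alleles ≥ 2 — and applied to member cells; the
0.5 threshold is a configurable surrogate for a model-based call, chosen
because a doubled genome keeps both haplotypes ≥ 2 wherever the
pre-doubling state was at least {1,1}, while deletion-dominated undoubled
genomes rarely reach it. Aberrant/deleted/amplified fractions follow the
baseline rules exactly (unordered {1,1} vs {2,2}; either allele below /
above the expected allele copy number 1 vs 2), so doubling a profile and
shifting the baseline commute — an identity the tests assert exactly. A
bin can be simultaneously deleted and amplified ({2,0} against a diploid
baseline), and aberrant ≤ deleted + amplified holds bin-wise. The
subclonal fraction compares each cell against the per-bin modal state of
the whole dataset. Locus status uses the overlap-weighted majority state
of the bins a locus touches: LOH when one allele is lost entirely and the
total is below the baseline total, copy-neutral LOH when the retained
allele alone reaches it.

## Interval-event phylogeny

Distance: for one haplotype on one chromosome, the minimum number of
contiguous ±1 events from parent to child is the sum over loss and gain
phases of the positive increments of the required per-bin change; a
haplotype at 0 in the parent and positive in the child is unreachable.
The decomposition also yields an explicit optimal event list whose replay
is asserted everywhere. Intermediates never leave the per-bin
[min(parent, child), max(parent, child)] envelope, so the closed form
matches breadth-first search on the copy-capped event graph — verified
exhaustively for all 4⁵ × 4⁵ five-bin haplotype pairs, on random ten-bin
pairs, and (for haplotype additivity) against a joint-state BFS. Events
are unit-cost; a cost-|delta| variant of the recurrence is the documented
alternative but is not asserted as the published model's variant.

WGD on an edge costs one event and is searched in two orderings — before
or after the edge's interval events; interleaved placements are not
searched (they can matter only when an event spans the doubling, which
the generator never produces and real segment profiles make
unidentifiable anyway). At most one WGD per root path, gated top-down.

Tree search enumerates every rooted multifurcating leaf-labelled topology
over the clones (≤ 8; above that an error points to the greedy mode,
which builds a minimum event-count arborescence over the observed clones
only). Ancestor profiles per topology are set per bin per haplotype by a
Sankoff dynamic program under linear cost with a distance-transform
transition, with candidate states restricted to the [min, max] interval
of descendant clone states and 0 forbidden above any positive descendant
(irreversibility). An earlier rule that clipped the parent's state into
the descendant range was abandoned: it dragged ancestors toward the root,
so a truncal gain privately reverted in one clone was re-paid on several
edges and the true topology scored worse than rearrangements. The linear
relaxation itself can still fragment multi-level runs, so the best twelve
topologies by relaxed cost get a local refinement pass that tries each
descendant clone's full profile (and the parent's) at every internal
node, keeping changes that do not increase the interval-event total and
preferring ancestors that coincide with observed clones — the
configuration chain-like truths actually have. Ties between equally
parsimonious trees break toward fewer internal nodes, then lexicographic
topology order; zero-event internal edges are contracted. Every returned
tree is replay-validated edge by edge.

Event classification on an edge: losses whose covered bins all end at 0
are LOH; an LOH whose retained allele ends above the expected allele copy
number (doubled below a WGD) over the same interval is copy-neutral;
other losses are deletions; positive events are gains.

## Concordance

The identical-window proportion restricts to bins where at least one
profile is aberrant against its own WGD baseline, then counts
(length-weighted) equal unordered allele-specific pairs — or equal rounded
totals for bulk segment inputs, since "identical assignment" is ambiguous
for total-only callers; both modes are provided. When exactly one profile
of a pair is doubled it is halved first, so diagnosis/relapse pairs
straddling a WGD remain comparable (switchable). With no qualifying
windows the result is flagged undefined, never 0. Bulk segment tables are
summarised as overlap-weighted median total copy number in 1,000-bp bins
(the printed convention for the bulk path; configurable — it is much finer
than the single-cell grid, whose consensus path defaults to the analysis
bins); uncovered bins are missing and handled pairwise-complete by the
Pearson matrix. Sample clustering is average linkage on 1 − r with missing
correlations at the maximal distance 2.

## Pipeline, seeds, determinism

`run_pipeline` chains simulate → infer → clones → metrics → phylo →
concord, writing every stage's output as TSV/Newick/DOT plus a
`summary.json` with sorted keys and no timestamps or paths. All
randomness derives from the single config seed through named SHA-256
substreams (`stage_seed(seed, stage)`), so reruns are byte-identical —
asserted by hashing the outputs of two independent runs. Config files are
YAML, validated field by field with unknown keys rejected.

## Experiment sizes

Chosen so the full suite and the acceptance script each run in a few
minutes on one CPU: clone-recovery panels use ten seeds of 1,000 cells on
the ~110-bin scaled genome; edge-replay uses fifty 2–5-clone
reconstructions; tree recovery uses twenty 4-clone chain truths on hg19
lengths at 2.5 Mb bins (589 bins), drawn with two rejection filters fixed
in advance — private events pairwise non-overlapping, and every edge's
event list minimally expressed (its length equals the interval-event
distance it induces). The second filter makes "the simulated truncal
share is 90%" well defined: without it, boundary-coincident truncal pairs
compress under parsimony and the recovered share falls below the nominal
value by construction rather than by method error.

## Known limitations

Per-cell calling ignores joint structure across cells, GC/mappability
correction and reference-panel phasing; the ×2 ploidy ambiguity is
resolved by grid refinement plus a lowest-ploidy tie-break, which will
call a *perfectly* balanced tetraploid genome diploid (only allelic
imbalance or a mixed-WGD subclone structure can break that degeneracy,
in this framework as in any RDR/BAF method). The ancestor optimisation is
a heuristic bound on full Steiner parsimony; exhaustive topology
enumeration is practical to 8 clones. The WGD call is a threshold rule,
decided per clone. Noise cells are modelled as bin-wise independent
corruption, which flatters any distance-based exclusion rule relative to
real correlated artefacts.
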