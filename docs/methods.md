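# Methods

## Model and assumptions

`coopmod` treats a cellular process as a set of interacting functional
modules and asks which *pairs* of modules cooperate.  Its object of
study is the weighted physical interaction (WPI) network:

* **Nodes** are genes.  The universe is the set of genes appearing in
  the protein-interaction or regulatory data (plus any caller-supplied
  extras); expression-only genes are excluded, because every network
  quantity (N, NL_i) is defined over physically connected genes.
* **Links** are physical: one undirected link per protein-interaction
  pair, one directed link per regulatory (TF → target) pair.  For link
  *counting* the direction is ignored; a pair connected by both kinds
  counts as two links.  Direction is retained as metadata because the
  correlated-gene typing and the relationship graphs need it.
* **Weights** `CopL_i` are co-expression degrees: the number of genes
  whose expression profile has Pearson `|r| >= 0.683` with gene *i*.
  Both signs count — strongly anti-correlated genes are biologically
  coupled.  The sign is stored on each co-expression edge but unused
  downstream.  The threshold is closed (`>=`) at exactly 0.683; the
  boundary case is measure-zero in real data and a closed comparison is
  the simpler contract to test.  Rows of the expression matrix with any
  missing value are dropped (and counted) at load time; constant
  profiles are skipped in the correlation pass because their
  correlation is undefined.

The key modelling assumption is that a gene important to the process is
broadly co-expressed (high `CopL`), and that module cooperation shows up
as heavy genes linked *above expectation* to both modules at once.  The
expected number of links between gene *i* and a module of size M is
`(M/N)·NL_i` — the share of i's links that a uniformly random M-gene
module would receive.  Strict inequalities are used throughout: a gene
must exceed its expectation, not meet it.

## The four scores

The verbal definitions of the four scores admit several algebraic
realizations; the forms below are this package's fixed choices, kept
behind four small functions so alternatives can be swapped in:

* `consistency_score` (CT): signed weight sum with strict
  above-expectation indicators, summed over genes *outside* the two
  modules.  Including members would double-count module-internal
  structure; mediators inside a module instead enter through the
  mediation score.
* `cmratio`: the plain Jaccard ratio of the two genes'
  link-neighbourhoods.  It is symmetric, bounded in [0, 1], and equals
  the shared-partner count normalized by all distinct partners.
* `mediation_score` (CoopMed): `R ·` the best single-mediator product
  `CMRatio(i, j) · CT({i}, {opposite anchor})` over module members i,
  clamped at zero, with `R = 0.9` the probability that a reported
  physical link is real.  One mediator, not a sum: the score asks
  whether *some* reliable route exists, and summing would reward
  redundant routes that the greedy search then cannot distinguish.
* `cooperation_score` (MCoop): seed consistency plus a per-member
  `max(direct, mediated)` term.  No normalization by module size — the
  greedy acceptance rule (score must not drop below the running
  maximum) already rejects non-contributing genes, and a size
  normalization would bias the search toward tiny modules.

## Seed selection and the spanning algorithm

All gene pairs that can score non-zero are enumerated (a pair can score
non-zero only if some weighted gene is linked above expectation to one
of its endpoints); their consistency scores are computed and the pairs
strictly above the 99th linear-interpolation percentile of the
*non-zero* score distribution become seeds.  With many small negative
scores in sparse data the percentile can be negative, in which case
negative-score pairs become seeds too; the rule is kept as stated
rather than clamped, and such seeds typically die in filtering.

Each seed (s, t) is grown by the spanning algorithm, rendered exactly
from its recursive definition but executed iteratively so depth is
bounded only by gene count:

1. The visit list starts as all genes except s and t; the running
   maximum starts at the seed's consistency score and is *shared*
   between the two module extensions.
2. From the current gene y, the single unvisited neighbour *i* with the
   largest CMRatio is taken (ties broken lexicographically); *i* is
   removed from the visit list unconditionally.
3. If the pair's cooperation score with *i* added stays `>=` the
   running maximum, *i* is kept and the maximum updated; the chain
   continues from *i* only if `CT({i},{center}) >= CT({y},{center})`
   (center = the opposite anchor).  Otherwise *i* is removed from the
   module — but never restored to the visit list (intentional pruning).

Two consequences of this design are worth knowing.  First, modules grow
as *chains*: each step extends from the most recently accepted gene, so
a module's reach depends on the existence of a CMRatio-guided path with
non-decreasing consistency.  Second, because each gene's consistency
with the *opposite anchor* gates continuation, chains cannot pass
through low-consistency connector genes into new territory, which makes
the search strongly local.  Both behaviors are verified against an
exhaustive oracle in the test suite (the greedy score never exceeds the
exhaustive optimum over connected disjoint extensions, and attains it
on fixtures with a unique monotone path).

Internally the spanning uses per-seed caches of singleton consistency
scores and CMRatios plus an incremental update of the per-member score
terms (with an undo record for rejected genes); the incremental total
is exactly the from-scratch cooperation score, and the tests assert
this equality.

**Merging and filtering.**  Two modules are highly overlapped when more
than 2/3 of *either* module's genes lie in the other (tested against
each module's own size, strict inequality: an overlap of exactly 2/3
does not merge).  Merging is iterative to a fixpoint, highest overlap
ratio first, ties by lexicographic module-id pair; the merged module
keeps the smaller id.  Pairs whose modules merged together, pairs still
satisfying the overlap rule, and pairs with a module below 3 genes are
dropped; pairs that became identical keep the highest-scoring
representative.  Merged pairs retain their original spanning score with
a `merged` flag — re-scoring unions would conflate the search objective
with the reporting.

## Randomization nulls

Correlated-gene significance uses degree-preserving edge swaps:
undirected double-edge swaps for protein links and directed two-arc
swaps for regulatory links, both rejecting self-loops and duplicate
edges.  `swaps_per_edge × |edges|` swap *attempts* are made per edge
set (default 10 per edge), a standard mixing budget.  Empirical
p-values use the add-one rule `p = (1 + #{null >= obs}) / (1 + n_random)`
with `n_random = 1000`, so the attainable minimum is 1/1001 ≈ 0.001 and
p = 0 is impossible.  One ensemble is generated per run and its link
counts tabulated for every module of every pair simultaneously — the
nulls are exchangeable across genes and modules, and sharing them keeps
a multi-pair run at the cost of a single-pair one.

A gene is a correlated gene of a pair when at least one of its three
counts (protein, regulated-by, regulates) is significant toward *each*
module at `alpha = 0.05` **and** the significant evidence matches one
of the five cooperation patterns (A: protein to one module + regulated
by the other; B: protein to one + regulates the other; C: protein to
both; D: regulated by both; E: regulates both).  A gene satisfying
several patterns reports all of them; the primary label follows the
priority C > D > E > A > B (symmetric patterns first).  The one
evidence combination matching no pattern — regulated by one module
while regulating the other — is excluded, with a debug log.  No
multiple-testing correction is applied across genes; the per-gene
p-values are reported so users can apply one.

Module-level correlation checks compare (a) within- and between-module
physical link counts against the same rewired nulls and (b) within- and
between-module counts of strongly co-expressed pairs (`|r| >= 0.683`)
against expression matrices in which each gene's profile is permuted
*independently* across conditions — a global (same-for-all-genes)
permutation would leave every pairwise correlation unchanged and test
nothing.

## Gene-set association and graphs

For a pair with C correlated genes in a universe of G genes and a
reference set of B genes overlapping b of them, significance is the
hypergeometric upper tail P(X ≥ b), computed via the survival function
(stable for G in the thousands); pairs with p < 0.05 (strict) are
significant.  G defaults to the WPI network size so all quantities in
the test share one universe; a fixed genome size can be supplied
instead.  Phase-significant pairs are ranked by b (ties by p, then pair
id), top 3 per phase.

The cooperative module network has one node per retained module and one
undirected edge per pair.  Per-phase relationship graphs admit only
regulators from the phase's regulator table (a curated
transcription-factor / CDK / cyclin / cell-division-cycle list per
phase ships with the package and can be overridden) that are correlated
genes of some pair; significant protein evidence draws undirected
edges, significant regulatory evidence directed edges (module → gene
node when the module's factors regulate it; gene node → module when it
regulates the module).  A regulator contained in modules is represented
by each containing module (one edge per container, with provenance);
parallel edges of identical endpoints/direction/type collapse to one
edge carrying the list of mediating regulators; isolated nodes are
pruned.  GraphML export is attribute-lossless; SIF and TSV keep only
edge types.

## Synthetic benchmark

The generator plants a known cooperative structure: two dense protein
modules (8 genes each by default, intra-module edge probability 0.85
plus a connectivity backbone), three mediator genes each linked to
62.5 % of both modules, an optional transcription factor regulating
half of each module, and 200 background genes with sparse random edges
(p = 0.015).  Expression is a shared latent profile (a unit-variance
sinusoid over 17 conditions, emulating periodic expression) plus
independent Gaussian noise (sd 0.2) for planted genes, and pure noise
for background genes — so planted genes get high co-expression weight
(pairwise r ≈ 0.96) and background genes essentially none.  A small
pool of background regulators with random targets (6 TFs, p = 0.04) is
included so the directed edge set is large enough for degree-preserving
swaps to mix; without it a lone planted TF's arcs could never be
rewired and every regulatory null would be degenerate.

What the benchmark does *not* emulate: scale-free interactome topology,
correlated measurement noise, condition-dependent interactions, or
overlapping module membership.  Passing tests on it demonstrate
correctness of the machinery (scores, nulls, bookkeeping,
reproducibility), not performance on real interactomes.

**Known limitation (measured, not hidden).**  On this benchmark the
greedy pipeline recovers planted *mediators* well whenever any module
pair survives filtering, but recovers the planted *module pair* itself
poorly: `scripts/acceptance.py` reports the mean best-pair Jaccard
overlap with the planted modules (~0.3 at defaults) alongside the mean
mediator recovery fraction (~0.5, concentrated in replicates with
surviving pairs).  The cause is structural.  Under the consistency
score, a candidate seed spanning two separate dense modules pays a
penalty of one `CopL` for every co-member exclusive to either side,
while gaining only the bridging mediators' weights — so the
top-percentile seeds are always pairs *within* one dense module, and
the chain-continuation rule (consistency must not decrease) prevents a
chain from passing through a mediator into the second module.  The
acceptance suite retains an end-to-end recovery check at a stringent
bound (Jaccard ≥ 0.8 with mediator recovery in 18 of 20 replicates),
which the current search does not meet; it is kept failing rather than
relaxed, as an honest statement of the greedy search's reach.  Sharper
recovery would require either a different seed objective (e.g.
penalty-free bridging) or a search that re-opens chains, both outside
the present scope.

## Numerical and reproducibility choices

* Percentile: NumPy's linear-interpolation percentile; seed selection
  is strictly greater.
* All tie-breaks (neighbour choice, merge order, output ordering) are
  lexicographic, making every stage deterministic given inputs and
  seed.
* One global seed fans out to per-stage seeds by SHA-256 hashing of the
  stage name (kept below 2^31), so stages rerun independently yet
  reproducibly; reruns are byte-identical except for wall-clock
  timestamps in the run report.
* Problem sizes in the shipped tests and acceptance script — networks
  of ≤ 30 genes for exact oracle comparisons, ≤ 10 genes for exhaustive
  spanning enumeration, 20 seeded replicates of the default benchmark
  for recovery, 1000 null draws for the type-I check — were chosen as
  the smallest scales at which each property is meaningfully exercised.
* Empirical p-values are never zero (add-one rule); hypergeometric
  tails are exact to 1e-12 against rational-arithmetic enumeration for
  small universes.
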