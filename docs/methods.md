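# Methods

`rnaphylo` implements a structure-constrained total-evidence phylogenetic
workflow for ribosomal-RNA data: nucleotide homology is fixed a priori
where the secondary structure supports it, length-variable regions that
cannot be aligned with confidence are handed to dynamic homology, and
molecular and morphological evidence are combined under congruence-based
weighting.  This note records the models, the algorithmic choices made
where the design was genuinely open, and what the synthetic benchmark does
and does not demonstrate.

## Structure-annotated alignments and region classification

The homology substrate is an aligned residue grid with two per-column
masks.  The pairing mask marks paired sites with three bracket families —
`()`, `{}`, `<>` — encoding nesting levels, with the third level reserved
for crossing (pseudoknot/tertiary) interactions; `.` marks unpaired
columns and `*` columns inside regions of ambiguous alignment.  Likelihood
machinery ignores level-3 bonds.  The helix mask labels contiguous column
runs with one character per helix.

Maximal `*` runs are classified by structural context: runs flanking a
helix terminus are regions of expansion and contraction (REC), interior
unpaired runs are non-pairing regions of ambiguous alignment (RAA).
Regions of slipped-strand compensation (RSC) cannot be diagnosed from the
masks — the published classification relies on expert inspection — so RSC
is accepted only through an override table.  RAAs inside hairpin (terminal)
loops are lumped with the adjacent REC into one dynamic-homology fragment,
because nucleotides migrate between a stem's tip and its terminal loop;
the lumping operator is idempotent and the intervals always tile the
column range.

Helix homology is audited by covariation: a base-pair bond counts as
*supported* when at least two distinct canonical pair types (A:U, U:A,
G:C, C:G and the G:U/U:G wobbles) occur across the taxa, i.e. at least one
compensatory or semi-compensatory substitution is observed.  Protonated
A:C pairs are counted as mismatches by default (a toggle treats them as
semi-canonical).  A helix confined to one lineage is excluded from every
structure-aware analysis and its presence/absence is coded as a binary
character with polarity 1 = absent.

## Substitution models

Unpaired (loop) columns evolve under GTR+I+G.  Paired (stem) columns are
recoded as one base-pair character per bond and evolve under one of two
reversible pair models:

* **7-state model** — the six canonical pairs as distinct states plus one
  lumped mismatch state MM; the most general reversible model on those
  states (21 exchangeabilities, 7 frequencies; **26 free parameters**
  after removing the rate scale).  Reversibility leaves pair reversal
  (A:U vs U:A) asymmetric up to detailed balance.
* **16-state model** — all ordered dinucleotides, with exchangeabilities
  collapsed into five classes: single substitutions, double substitutions
  and double transversions among the six canonical states, single changes
  between a canonical and a mismatch state, and single changes between
  mismatch states; double changes through a mismatch state are forbidden
  (**19 free parameters**: 5 classes − 1 scale + 15 frequencies).
  "Double transversion" means both positional changes are transversions
  (purine↔pyrimidine per position); a double change with at least one
  transition is a "double substitution".

All generators use the reversible parameterisation `q_ij = s_ij π_j`,
scaled to one expected event per unit branch length.  Transition
probabilities come from the eigendecomposition of the π-symmetrised
generator, falling back to scaling-and-squaring (`scipy.linalg.expm`) when
a stationary frequency is zero.  Rate heterogeneity uses the usual
invariant-sites class plus a discrete gamma with 4 equal-probability
categories (category means via the incomplete gamma); heterogeneity is
always part of the loop model and optional (default off) for the pair
models.  Likelihoods are computed by Felsenstein pruning with ambiguity
and missing data marginalised; IUPAC codes expand to state sets
throughout.

## Bayesian inference

Metropolis–Hastings with flat priors made concrete as uniform(0, 100) on
rate parameters, the uniform Dirichlet on frequency vectors,
uniform(0, 10) on branch lengths and uniform on unrooted topologies.
Moves: a uniformly drawn NNI (optionally SPR) neighbour — NNI
neighbourhood sizes are constant across binary topologies, so the proposal
is symmetric — a branch-length multiplier with its Hastings correction, a
symmetric two-component transfer on a frequency vector, and a rate
multiplier.  Defaults: 25% burn-in, sampling every 100 generations,
two independent runs from random starting trees; Metropolis coupling is
available in the configuration but off by default, as nothing requires it
at the scales exercised here.

Model comparison uses the harmonic mean of the sampled log-likelihoods
(computed with a stable log-sum-exp) and log Bayes factors as differences
of harmonic means.  The harmonic-mean estimator is known to be unstable
with heavy upper tails; it is implemented as the published comparison
device, and the four compared layouts (uniform GTR+I+G, stem/loop
partitioned GTR+I+G, GTR+I+G with a 7-state stem model, GTR+I+G with the
16-state stem model) differ by hundreds of log units on coevolving stems,
far beyond that instability.  Convergence diagnostics: the effective
sample size `n / (1 + 2 Σ ρ_k)` with the autocorrelation sum truncated at
the first non-positive consecutive pair (a constant trace is degenerate
and reported as n), and the Gelman–Rubin potential scale reduction factor
across runs with the conventional ≤ 1.05 threshold.  Majority-rule
consensus uses strict majority: splits at exactly 50% are excluded.

## Parsimony

Static molecular characters are unordered with the gap as a fifth state;
morphology and structure characters are unordered multistate characters
(`?` and `-` both read as missing — inapplicability is not distinguished).
Scoring is Fitch's set method over bitmask state sets, vectorised across
columns; polytomies are scored as an arbitrary binary resolution.  Search
is random-addition Wagner building followed by branch swapping — NNI, a
*complete* SPR neighbourhood (both sides of every edge are prunable; the
root-containing side is handled by rerooting along the edge), or a
TBR-style variant that additionally reroots the pruned part — with an
optional parsimony ratchet (double the weight of ~25% of columns, swap,
restore, swap).  All equally optimal distinct topologies are retained up
to a cap (default 10,000).  Searches are deterministic under a fixed seed.

The ensemble consistency index is Σmin/length and the retention index
(Σmax − length)/(Σmax − Σmin), uninformative characters included; an
all-invariant matrix reports CI = RI = 1 with degenerate meaning.
Supports: jackknife with independent column deletion at probability
e⁻¹ ≈ 0.368 (the resampling-equivalence convention), reporting split
frequencies across replicate strict consensi; Bremer decay via
reverse-constraint searches that penalise trees containing the clade, by
default restarted from the optimal trees (cheap variant) rather than from
fresh builds.  Tree fusing exchanges subtrees with identical leaf sets
between tree pairs — compared by rooted clade sets, so three-leaf
rearrangements are seen — and keeps improvements; the fused score never
exceeds the best input.

## Direct optimization

A cost regime is the (gap extension : transversion : transition) triple,
named by its digits in that order ("412" = gap 4, transversion 1,
transition 2 — parsed strictly even though transition > transversion is
unusual).  Gap cost is linear: the published regimes name only a gap
*extension* cost, so no opening penalty exists anywhere in the pipeline.

Fragment cost on a tree is a documented upper-bound heuristic of the exact
tree-alignment cost: a single post-order pass aligns children's median
sequences pairwise (Needleman–Wunsch over bitmask state sets with a
per-regime 32×32 cost/median lookup table), threads the leaf rows through
the tracebacks into an implied alignment, and reports the minimum cost of
that implied alignment on the fixed tree (per-column Sankoff over the five
states A, C, G, U, gap).  Because the implied alignment is a genuine
alignment, the reported cost can never undercut the true optimum, and
re-scoring the implied alignment statically reproduces it exactly.  The
thorough variant (default for standalone scoring) retries every leaf-edge
rooting and both traceback tie-break preferences and keeps the cheapest
implied alignment; tree searches use the single-pass variant for speed.
On random quartet toys the thorough variant attains the enumerated exact
optimum in ≳95% of cases.  There is no iterative-pass refinement, no
affine gaps, and no attempt at exact tree alignment beyond the test
oracles.

Combined scoring: static columns and structure characters are scored by
Fitch at unit weight regardless of the regime (equal weighting under
static homology), fragments by the DO heuristic under the regime, and
morphology by Fitch times the regime's morphology weight
`L_mol(regime) / L_mol(111)`, which keeps the morphological contribution
approximately constant across regimes.  Score components are kept separate
in the reports so any totalling convention can be assembled.

## Congruence and sensitivity

ILD is the Mickevich–Farris normalised incongruence length difference
`(L_combined − Σ_k L_k) / L_combined`, with partition lengths computed
under the same regime and mode as the combined run (fragments under DO,
static columns under Fitch).  The regime minimising ILD is selected.
Ties break to the lexicographically first label and are flagged; a tie
means either equal normalised values or equal *raw* incongruence steps
(`L_combined − Σ L_k`) — in the latter case the normalised values differ
only through the combined-length denominator, which would mechanically
favour regimes that inflate every length, so the raw count is the
meaningful comparison.  The
sensitivity grid records, per monitored clade and regime, whether the
clade appears in the strict consensus of that regime's optimal trees.
Which data blocks form the ILD partitions is a per-run configuration
(different genes, genes × morphology, …); the pipeline default splits the
molecular data into two interleaved groups standing in for the two genes.

## Synthetic ground truth

The generator emits exactly the statistical structure the analysis
assumes: a Yule tree; stems simulated as coevolving pair states under the
7-state model (G:C-rich, ~6% mismatch at stationarity) and projected to
two bracket-masked columns; loops under GTR+I+G with A-rich stationary
frequencies (38% A, mirroring the adenosine bias of unpaired rRNA);
designated segments evolved under substitutions plus a symmetric
Poisson/geometric indel process and emitted both as `*`-masked blocks and
as unaligned fragment files; one clade-restricted helix whose absence
elsewhere gives a presence/absence character with known truth; and an
Mk-evolving morphological matrix on the same tree.

Defaults (chosen once): 16 taxa; 60 stem pairs in four helices + 200 loop
sites (~330 pre-aligned columns); three ambiguous regions of mean length
8 nt with indel rate 0.35 relative to substitutions and geometric length
parameter 0.5; a lineage-restricted helix of 4 pairs on a clade of about a
third of the taxa; 18 binary Mk characters at rate 0.6.  The tree's mean
root-to-tip path is normalised to 0.5 substitutions/site with internal
branches floored at 0.08 — a deliberately *strong-signal* regime in which
every split leaves on the order of ten synapomorphies, so topology
recovery is expected of any correct method.  A smaller default (~160
columns, no branch floor) was rejected because the simulated data then
genuinely prefer slightly wrong trees (the optimum scores below the true
tree), which tests method correctness against an unattainable standard.

What passing recovery tests show: the pipeline's machinery is internally
consistent and statistically sound under its own generating assumptions.
What they do not show: robustness to model misspecification, alignment
error in the pre-aligned portion, base-composition heterogeneity across
lineages, or the deep, unevenly sampled divergences of real chelicerate
rRNA — none of which the generator emulates (no covariance-model sequence
realism).

## Problem sizes and numerical conventions

Tests and drivers run at reduced scale: quartet/quintet likelihood
oracles, ≤ 7-taxon exhaustive searches, 16-taxon end-to-end runs, MCMC in
the 10⁴–10⁵-generation range, and four cost regimes in the DO drivers;
these sizes are the package's chosen desk-scale study conditions.
Score comparisons use an absolute tolerance of 1e-9; transition-probability
matrices are clipped at 0 and renormalised row-wise; coordinates are
0-based half-open internally and 1-based inclusive in every report.  The
exact mask-record naming inside structured FASTA files is configurable
(`#pairing`/`#helices` by default), since archive conventions vary.

## Known limitations

* The DO heuristic is an upper bound; on adversarial fragments it can
  exceed the exact tree-alignment cost (never undercut it).
* The TBR variant approximates true TBR by rerooting the pruned part at a
  bounded number of positions.
* Harmonic-mean marginal likelihoods inherit the estimator's instability;
  stepping-stone methods are deliberately out of scope.
* Mk morphology simulation uses equal state frequencies and a single rate
  per matrix; no ascertainment-bias correction is applied.
* Polytomies are parsimony-scored as one arbitrary binary resolution.
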