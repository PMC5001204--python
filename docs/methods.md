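# Methods

## Scoring model

Under two-condition differential expression, per-gene p-values are modelled
as a beta-uniform mixture (BUM)

    f(p) = λ + (1 − λ) · a · p^(a−1),   p ∈ (0, 1],  λ ∈ (0,1),  a ∈ (0,1),

a Uniform(0,1) noise floor of weight λ plus a Beta(a,1) signal component
concentrated near zero. The mixture is fitted by bounded maximum likelihood
(L-BFGS-B over (λ, a) ∈ [10⁻⁶, 1−10⁻⁶]², 16 deterministic starts on a
λ×a grid, best likelihood retained). The surface is ridge-shaped near the
pure-noise corner — λ→1 with any a and a→1 with any λ describe the same
uniform density — so null-data recovery is asserted on the fitted *density*,
not on the raw parameters.

The estimated false discovery rate among genes called at threshold τ is
π·τ / F(τ), with π = λ + (1−λ)a the noise-density upper bound and F the
mixture CDF. Inverting for a user-chosen FDR gives

    τ(FDR) = [ (π − FDR·λ) / (FDR·(1−λ)) ]^(1/(a−1)),

clamped to ≤ 1 and strictly increasing in FDR, and the signed node score

    s(p) = (a − 1)(ln p − ln τ),

zero at τ, positive below, negative above. The FDR is thus the module-size
dial: every threshold in the pipeline (SDG α = 0.01 uncorrected, miRNA
α = 0.05, default module FDR 10⁻⁴, five active modules at depth 2 and
overlap 0, hub degree ≥ 4, keywords "drug"/"metabolism" with top six KEGG
terms) lives in the pipeline config, not in stage logic.

## Maximum-weight connected subgraph search

The maximal module is the connected subgraph maximising Σ s(p). The solver
works per connected component:

1. **Safe reduction** — iteratively strip degree ≤ 1 nodes with
   non-positive score (they can never improve any solution).
2. **Exact search** when the reduced component has ≤ 14 nodes: a bitmask
   scan over all induced subsets with flood-fill connectivity, guaranteed
   optimal. This covers the property-test regime and small response
   networks.
3. **Prize-collecting heuristic** otherwise: contract each
   positive-score connected component into a supernode whose prize is its
   summed score; starting from the best supernode, repeatedly merge the
   supernode whose cheapest bridge through negative connector nodes
   (multi-source node-weighted Dijkstra, entering node v costs
   max(−s(v), 0)) leaves a strictly positive net gain; finally shed
   negative leaves the bridges left behind.

Ties break on the lexicographically smallest gene set, making the search
deterministic. The aggregate score, not the node identity, is the
contract tested against exhaustive enumeration, since distinct node sets
can attain the same optimum.

The FDR scan evaluates the module across a grid (default 10⁻⁸…0.05). With
ground truth it records true-positive rate |M∩T|/|T| and precision
|M∩T|/|M| and selects the F1-best row (ties: smaller module, then smaller
FDR); without truth it takes the smallest FDR whose module size falls in a
configured band (default 10–300), falling back to the size closest to the
band midpoint when none does.

## Multiple active modules

The complementary multi-module search aggregates z_i = Φ⁻¹(1 − p_i) as
z_A = Σz/√k for a size-k candidate set and standardises it against the
Monte-Carlo mean and sd of random k-sets (200 draws per size, seeded), so
scores are comparable across sizes. Search grows greedily from the
lowest-p start genes (three candidate starts per requested module), never
leaving the radius-2 ball around the start; growth proceeds to a size cap
(default 30) taking the locally best neighbour even through score dips,
and the best-scoring prefix is kept — plain first-dip stopping stalls on
calibration plateaus. Returned modules are ranked by calibrated score and
filtered to pairwise overlap ≤ the threshold (|A∩B|/min(|A|,|B|); 0 means
disjoint); fewer than the requested number may survive, with a warning.
p-values are clipped to [10⁻¹⁵, 1−10⁻¹⁵] before the normal quantile.

## Enrichment and miRNA integration

Enrichment is the upper hypergeometric tail P(X ≥ x) with the supplied
universe as population, BH-adjusted across tested sets; it deliberately
does not emulate web-service annotation tools (no EASE-style score, no
ontology-graph propagation), so published p-values from such tools are
context, not targets. Relative abundance E(i) = S(i)/N(i) uses the
query-set size as denominator N; a per-pathway denominator (pathway
coverage) is available behind a flag, since the statistic's verbal
definition admits both readings.

Target pairs from multiple databases are unioned by default
(min_sources = 1) with an optional minimum-support or required-source
(validated database) rule. The anti-correlation predicate is strict:
a gene log fold change of exactly 0 or a miRNA fold change of exactly 1
never counts. The network builder applies whatever significant-miRNA table
it is given and *logs* rows violating the p < 0.05 rule instead of
dropping them silently — the published worked-example edge table itself
contains three such miRNAs, and reproducing its 8-gene/14-miRNA network
requires honouring the table while flagging the inconsistency. The same
honesty applies to function assignment: computed from the edge table, the
cancer term gains two miRNAs (miR-202, let-7g via EGLN2) that the published
function table omits although its prose names them; the computed assignment
is reported as-is.

## Synthetic scenarios

The generator emulates the study conditions end to end: a preferential-
attachment network (2000 genes, 4 edges per new node — heavy-tailed like
merged interactomes, mean degree ≈ 8; a desk-scale stand-in for a
10⁴-node interactome), a connected 30-gene planted module grown by seeded
random breadth-first expansion with a fixed random sign per gene,
log-normal expression (baseline N(8, 2) log2 units) with ±4 log2-unit
treated-arm shifts on module genes, replicate noise sd 0.5 and 7
replicates per arm, a 334-miRNA panel with 6% significant members whose
fold change opposes their planted targets' signs, and 50 pathway sets
(sizes 10–40) of which 5 draw at least half their members from the module.
Every generator is a pure function of its arguments including the seed;
scenario sub-stages use streams spawned from one master seed.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: read-level noise and normalisation artefacts,
correlated genes outside the module, hub-biased differential expression,
annotation incompleteness, identifier mismatches between databases, and
miRNA regulation that is not expressed as clean sign opposition. The
planted-recovery benchmark (F1 ≥ 0.8 over 20 seeds; in practice ≈ 1.0 at
the default effect size) therefore validates the machinery, not the
effect size of any real experiment.

## Numerical choices and degenerate inputs

- DE test: Welch t on log2 values (the test interface is pluggable; a
  rank-sum variant ships). Zero variance in both arms with equal means
  gives p = 1; with unequal means, the smallest positive float. p-values
  are clamped into (0, 1] before log-scoring.
- Genes present in the network but missing from the statistics table are
  assigned p = 1 (maximally negative score), logged.
- BUM fitting requires ≥ 50 points and rejects all-identical samples.
- Strict inequalities at both significance thresholds; miRNA direction
  from fold change relative to 1, with exact 1 flagged "ambiguous" and
  retained.
- Isolated SDGs are kept as nodes of the induced response network but can
  never join a module (search operates on connected structures).
- All tie-breaks (module selection, heuristic merges, greedy growth) are
  lexicographic on gene symbols; byte-identical outputs under a fixed
  config and seed are asserted in the test suite.

## Known limitations

- The MWCS heuristic is not exact above 14 reduced nodes; on adversarial
  score configurations it can miss bridges whose profitability only
  appears jointly. Exactness is guaranteed (and tested) in the small
  regime; the planted-recovery benchmark covers the large regime
  empirically.
- The z-score module search is a deterministic greedy stand-in for
  annealing-based search; it inherits greedy myopia beyond the
  best-prefix backtrack.
- Enrichment assumes the supplied universe is the correct background;
  universe misspecification shifts p-values globally.
- The bundled published tables carry printed precision only; computations
  on them inherit their rounding.
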