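# Methods

This note documents the models, rules and numerical choices behind
`cordkit`, and what the synthetic corpus does and does not emulate.

## Comparison enumeration

An experiment's design is a map sample → (factor → level). The *individual
factor method* groups samples by the levels of one factor at a time,
irrespective of the other factors, and emits every unordered level pair; a
design with 2, 3 and 2 occupied levels yields C(2,2)+C(3,2)+C(2,2) = 5
comparisons. The *grouped factor method* partitions samples by their full
level tuple and compares occupied cells **differing in exactly one factor**,
the shared levels forming the comparison's context. All-vs-all pairing of
cells was rejected: it grows quadratically in the number of cells and
produces comparison counts far out of proportion to the individual method,
whereas one-factor-differing pairing keeps the two methods' comparison
counts on the same order and gives every comparison a clean interpretation
(one factor varied, everything else held fixed). With a single factor the
two methods coincide.

Samples lacking a level for a factor are excluded from that factor's
individual-method groups and from all grouped-method cells. Level pairs are
oriented lexicographically; direction carries no meaning because queries
re-orient every comparison.

## Differential expression

Each probe is tested with an equal-variance two-group linear model and
empirical-Bayes variance moderation. Per probe: log2 fold change
Δ = mean(b) − mean(a), pooled variance s² on df = n_a + n_b − 2 degrees of
freedom (missing values reduce the group means' n and df; probes with fewer
than two values in either group are skipped). The prior (d₀, s₀²) is fitted
across the comparison's probes by the standard moment estimator on
z = log s²: with e = z − ψ(df/2) + log(df/2),

    ψ′(d₀/2) = var(e) − mean(ψ′(df/2)),    s₀² = exp(mean(e) + ψ(d₀/2) − log(d₀/2)),

where ψ, ψ′ are the digamma/trigamma functions and the trigamma inverse is
solved by Newton iteration. When the observed spread of variances is no
wider than sampling noise (non-positive excess variance), d₀ is unbounded
and the posterior variance is s₀² (taken as the mean sample variance), so
equal observed variances make shrinkage a no-op. The moderated statistic is
t = Δ/√(s²_post(1/n_a+1/n_b)) on d₀+df degrees of freedom with
s²_post = (d₀s₀² + df·s²)/(d₀+df); d₀ = 0 recovers the ordinary pooled
t-test exactly, which the tests exploit as an oracle, alongside an
independent cross-check against the Bioconductor reference implementation.
p-values are BH-adjusted within each comparison. A probe with zero posterior
variance and zero fold change is reported as t = 0, p = 1.

Defaults: α = 0.01 on the adjusted p, linear fold-change threshold 2.0,
minimum 3 samples per group at query time. These are the operative
significance rules; both are settable per query.

## Probe collapsing and ortholog harmonization

Within one comparison, significant probes (p_adj < α — significance only, no
fold-change cut at this stage) are grouped by gene symbol. A symbol whose
significant probes carry both positive and negative fold changes is removed
entirely (zero fold changes count as neither sign); otherwise the log2 fold
changes are averaged and the gene is kept if the *average* clears
log2(FC). The fold-change cut deliberately comes after the discordance
check: a weak opposite-direction probe still vetoes its gene. The
removed/analyzed ratio is tracked corpus-wide as the discordance rate,
counting gene-comparison events (the same gene removed in three comparisons
counts three times).

Native mouse/rat symbols are then mapped to human symbols via the corpus
ortholog table; unmapped symbols are dropped (counted), and two native
symbols colliding on one human symbol re-enter the discordance/averaging
rule (probe-count-weighted average, so the result equals collapsing the
pooled probes directly — collapse and harmonization commute for bijective
maps).

## Database build vs query

`cord build` applies α to probe-level significance and stores collapsed gene
tables **without** the fold-change cut (each row keeps the averaged log2fc
and the minimum adjusted p among the gene's significant probes), along with
per-comparison group sizes and species. `cord query` then applies its own α
(against the stored p_adj_min), fold-change threshold, species filter and
minimum group size. This keeps the query-time filters meaningful without
rebuilding; the one constraint is that a query's α is effectively capped by
the build α (default 0.01 at both stages) and its minimum group size by the
build floor of 2.

## Query, orientation and correlation

A comparison is retained for a query when every query gene is significant
there and, after flipping the comparison's sign so the *first* query gene is
upregulated, all query genes are upregulated ("same manner"). This makes the
query's fold changes positive in every retained column, so reported target
fold changes are ≥ the threshold. Candidate genes are scored by Pearson
correlation with the target over pairwise-complete comparisons (a gene
absent from a comparison — not differentially expressed there — is missing,
not zero; imputing 0 would fabricate agreement). Genes sharing fewer than
`min_shared` = 3 comparisons with the target, or with zero variance across
the shared ones, are excluded: a correlation over fewer points is
degenerate. The double-flip construction makes all correlation records
invariant to the stored direction of any comparison.

## Informative list size

The two methods' rankings are compared by percent overlap,
overlap(n) = 100·|top_n(A)∩top_n(B)|/n, on a grid n = 10…1000 step 10
(truncated to the shorter list). The curve is smoothed with a centered
moving average (window 5 grid points, reflecting at the edges) before taking
first/second differences per grid step. The informative size K is the
smallest grid point from which, over the entire remaining grid, |d²| stays
below 0.05 %-points/step and the local slope stays within 2× the scrambled
baseline's slope (plus the same 0.05 tolerance, so a flat plateau over a
flat baseline qualifies); if no such point exists the corpus-level default
K = 400 is used (clamped to the grid). The scrambled baseline permutes
*both* lists (n_reps independent permutations, seeded); for full-length
lists over G genes its expectation is 100·n/G. The window and tolerances are
exposed as function parameters; the defaults recover a constructed two-phase
curve's breakpoint to within one smoothing window and return the grid
minimum for an exactly linear curve.

The final similar list is the intersection of the two methods' top-K genes,
restricted to genes positively correlated under both methods and ordered by
the grouped-method r descending; the dissimilar list mirrors it at the
negative end. Genes whose correlation sign differs between methods appear in
neither. The method-comparison histogram log2(r_individual/r_grouped) is
computed over genes positive under both methods and summarized by its
median.

## Enrichment

Over-representation of the similar list in each supplied GMT collection is
scored by the one-sided hypergeometric tail P[X ≥ k] with BH across tested
sets; sets without overlap are omitted. The universe is the set of genes
observed anywhere in the corpus database — not the genome — because that is
the population the list was drawn from and it requires no external
annotation.

## Synthetic corpus

The generator emulates the corpus structure the pipeline consumes, with
known ground truth. Defaults (the study conditions used throughout the
tests): 50 experiments, 80% of which perturb the target; each experiment is
a 2×2 factorial (genotype × time) with 3 samples per cell; 2000 genes with 2
probes each; the target's log2 effect δ between genotype levels has random
sign and magnitude uniform on [1.5, 4]; a 30-gene module responds with
0.8·δ + N(0, 0.2²); background genes are independently perturbed at rate
0.10 with the same magnitude distribution (random signs, hence ≈ zero
correlation with the target); within-group sample noise sd 0.25 shared
across a gene's probes, probe noise sd 0.1; one probe's effect is
sign-flipped per gene-experiment at rate 0.0274 to exercise the discordance
rule; 30% of experiments are mouse, with a title-case native symbol table
and an ortholog map back to the human symbols. The effect floor of 1.5 log2
units keeps planted effects above the 2-fold reporting cut; sample sizes and
noise give the moderated test high power at 3v3, which is what makes ≥90%
module recall an expected outcome rather than a tuned one.

What the generator does **not** emulate: probe-sequence effects, batch
structure, correlated background modules, platform-specific missingness, or
isoform-level probe behavior. Passing recovery tests therefore demonstrates
the pipeline's correctness under its own assumptions (fold-change coupling,
independent background), not performance on real heterogeneous corpora.

## Determinism and numerics

All randomness flows through seeded `numpy` generators; experiment
directories, comparisons and gene tables are iterated in sorted order; TSV
output uses fixed float formatting (`%.6g` reports, `%.10g` database) and
`\n` line endings, so identical corpus + flags ⇒ byte-identical reports.
Database TSVs round-trip at 10 significant digits, which is why database
equality tests use a 1e-9 tolerance while in-memory reruns are exact.

## Known limitations

- Two-group contrasts only: no covariate adjustment, paired designs or
  time-course modeling; multi-level factors are handled as all level pairs.
- The grouped-method pairing rule (cells differing in exactly one factor) is
  a documented design choice; designs annotated with redundant or collinear
  factors can produce few or no grouped comparisons.
- Query-time α cannot exceed the build α (see build vs query above).
- Enrichment p-values are conditional on the corpus-derived universe; they
  are not comparable across databases built from different corpora.
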