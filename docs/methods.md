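# Methods

## Pooling designs and identifiability

A roster of N donors, each contributing one skin and one PBMC sample, is
pooled so that each donor's two samples land in *different* reactions.
After per-reaction genotype clustering, the observables are (i) which
cluster slots across reactions share a genotype (the same-donor partition)
and (ii), optionally, each slot's donor sex from Y-gene expression. A design
is *identifiable* when exactly one slot→sample mapping is consistent with
those observables.

**Dual strategy (2 samples/reaction, N reactions).** Donors, sorted by id,
are split into consecutive groups of three (the last group absorbs a
remainder of one or two). Within a group of m donors, m−1 block reactions
chain neighbours with alternating tissue (skin, pbmc, skin, …), so each
interior donor's pair spans one dual block. Each group leaves two samples
over — the first donor's PBMC ("head") and the last donor's unused tissue
("tail") — and these are paired into closing reactions: tails together,
heads together, and, when the group count is odd, one mixed-tissue closer.
The construction guarantees that any two genotype-linked reactions share
exactly one donor, so each equivalence class pins a unique donor and the
layout is identifiable *without* sex. N = 2 is refused: any "genetically
unrelated" addition would be the other donor's own paired sample, and the
resulting two-reaction swap layout is exactly 2-fold ambiguous.

**Triplet strategy (3 samples/reaction, 2N/3 reactions).** Requires N ≥ 6,
N ≡ 0 (mod 3), and enough donors of each sex. N/3 anchors are chosen
greedily on the sorted roster so the remaining 2N/3 fillers split evenly by
sex (error naming the limiting sex otherwise). Block j holds the anchor's
PBMC in the skin-side reaction and its skin in the PBMC-side reaction;
each reaction also receives one male and one female filler sample, with a
filler's second tissue rotated one block forward so no dual block shares
more than the anchor genotype. Genotype sharing pins the anchors and links
each filler's two slots, but within a block the male and female filler
classes span the same reaction pair — a 2-per-block symmetry (2^(N/3)
consistent assignments) that only the sex observable breaks. Generated
layouts are byte-reproducible: ordering and tie-breaks are lexicographic
throughout.

**Checker.** `check_identifiability` builds the noise-free observables from
the design's own ground truth, then counts, by depth-first enumeration with
min-domain ordering, the assignments of donors to anonymous equivalence
classes such that each class's donor occupies exactly the class's reaction
set, donors are used once, and (optionally) sexes match. This is exact; the
tests cross-check it against an independent brute force over all
per-reaction permutations (up to 3!^6 layouts).

## Synthetic data

The generator emulates what a pooled experiment yields after alignment; it
defines the default study conditions for every downstream test.

* **Donor genotypes**: per locus, minor-allele frequency ~ U(0.1, 0.5);
  per donor, alt copy number ~ Binomial(2, MAF) (Hardy–Weinberg).
* **Allele counts**: per cell and locus, depth ~ Poisson(mean_depth = 2);
  alt reads ~ Binomial(depth, p_g) with p_0 = ε, p_1 = 0.5, p_2 = 1 − ε and
  ε = 0.01. 300 loci, 200 cells per pooled sample.
* **Doublets**: each droplet is, with probability d = 0.05, the sum of two
  independently drawn member cells (cross-genotype when donors differ; with
  three equal pools, 2/3 of doublets are cross-genotype). Doublets replace
  singlets, keeping the emitted total at cells_per_sample × n_members.
* **Expression**: nine Y genes at Poisson rate 0.5 UMIs/gene/cell for male
  donors and 0.005 for female (a small mapping/ambient leak), plus 100
  background genes at 5 UMIs/gene/cell (~500 UMIs per cell). These rates
  put cluster-level y_pct near 0.9% for male clusters and 0.009% for female
  ones — two orders of magnitude apart around the 0.02% call threshold.

All randomness flows from one seeded generator (per-reaction streams are
spawned from (seed, reaction index)), so equal configs give identical data.

What it does **not** model: ambient RNA, inter-reaction contamination,
realistic transcriptome structure (dropout beyond Poisson, cell types),
related donors, or sex-chromosome aneuploidies. Passing tests therefore
demonstrate correctness of the decoding machinery under the stated
generative assumptions, not performance on any particular real dataset —
for real data the diagnostic outputs (y_pct table/histogram, concordance
scores, borderline flags) are the audit trail.

## Genotype clustering (EM)

Cells are clustered on sparse ref/alt counts with a K-component binomial
mixture, uniform weights: ℓ(c|k) = Σ_l [a_cl log q_lk + r_cl log(1−q_lk)].
The M-step sets q to the responsibility-weighted alt fraction, clipped to
[ε, 1−ε]; uncovered loci default to 0.5. Convergence: total log-likelihood
improvement < 1e-4; up to 200 iterations; best of 4 restarts (first seeded
k-means++ on mean-imputed per-cell alt fractions, the rest random hard
assignments; ties break to the lower restart index). Cells with zero covered
loci are reported `unassigned`. K is taken from the design (pool size), not
estimated. This is a deliberate desk-scale simplification of the
souporcell-style model — no remapping, no ambient-RNA term — and real
souporcell outputs can be substituted through `pairpool.io`.

**Doublets**: a cell is called a doublet when the best pairwise-mixture
likelihood (profiles averaged, q = (q_i + q_j)/2) beats the best singlet by
more than δ = 2.0 nats. At the default depth 2 the summed coverage of two
cells already separates well (recall 1.0 in the shipped runs); the
acceptance check uses depth 5.

**Consensus calls**: q < 0.1 → 0; q > 0.9 → 1; |q − 0.5| < 0.15 → 0.5;
otherwise no-call; loci with < 3 aggregate reads among the cluster's
singlets are no-calls.

## Matching and resolution

Concordance between two clusters = fraction of identical discretized calls
over co-called loci; fewer than 20 co-called loci is a *no-call*, distinct
from a low score (a Pearson correlation of allele fractions can be attached
as a diagnostic but never drives matching). Edges at score ≥ 0.9 form the
match graph; scores within 0.02 of the threshold are flagged borderline;
nodes matching two clusters in one reaction are surfaced as conflicts and
their sharing evidence is dropped (never auto-resolved).

Resolution is exact CSP over match-graph components: a component may take
any donor with a sample in each reaction it spans; donors are used at most
once per reaction; two components may share a donor only if none of their
reaction pairs was comparable (absence of a match is evidence only where
enough loci were co-called); an assigned donor's sex must equal every sex
call among the component's slots. Backtracking enumerates all solutions
(listed exhaustively up to 100): `unique`, `ambiguous` (all alternatives
reported, fixed slots separated), or `inconsistent` with the violated
constraint as witness. One deliberate deviation from naive expectation:
deleting a single anchor match from a triplet block does *not* create
ambiguity when sex calls are present, because per-reaction injectivity pins
the orphaned anchor slots once the fillers are fixed by their cross-block
matches; the enlarged solution set appears in the sex-free setting.

## Sex inference

y_pct = 100 × (Y-gene UMIs) / (all UMIs), summed over the cluster's singlet
cells (doublets are excluded — their mixed origin blurs the signal). Call =
male iff y_pct ≥ τ_male = 0.02 (percent), which sits ~2× above the female
expectation and ~45× below the male one under the default generator; the
per-cluster y_pct table (and histogram, via the CLI) is always written so
the separation can be audited on real data. A cluster with zero UMIs gets a
no-call rather than aborting the run; the resolver treats it as missing
evidence.

## QC

Cell filters before gene filters, following the stated order: cells keeping
≥ 200 and ≤ 4000 detected (nonzero) genes survive; then genes detected in
< 3 surviving cells are dropped. Filtering is idempotent and the report's
removed counts reconcile exactly with the dimension change. Cross-genotype
doublet removal drops exactly the barcodes the clusterer called doublets,
preserving order. Normalization scales each cell to 10,000 counts and
applies log(x+1); all-zero cells pass through. Note the synthetic expression
panel has only 109 genes, so pipeline runs on synthetic data must lower
`min_genes_per_cell` (the tests use 10); the defaults are meant for real
transcriptome-wide matrices.

## Problem sizes

The shipped tests and the acceptance script run the full pipeline at the
default conditions above (9 donors, 6 triplet reactions × 600 cells, 300
loci — a few seconds end-to-end), brute-force enumeration oracles up to
3!^6 layouts and 2^8 hard assignments, and 2000-locus closed-form checks.
These sizes were chosen so every claim is verified exactly or with ample
statistical margin while the whole suite stays interactive.
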