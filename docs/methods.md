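# Methods

## Problem setting

`wgdbench` benchmarks multi-species ortholog prediction in a clade shaped by
a single whole-genome duplication (WGD): three pre-WGD lineages and three
post-WGD lineages whose ancestor duplicated its genome, leaving every
homologous group with up to two post-WGD copies, one per chromosomal track
(A / B). Differential loss of those duplicates produces retention classes
0–IV; in class III the surviving copies span both tracks, so a single-copy
orthology method that groups them together is silently mixing paralogs —
the classic "trap". The toolkit implements two prediction algorithms
(cRBH, cRSD), a gold-group evaluation pipeline, and a simulator that
generates clades with known truth so that the whole chain is testable
without external data.

## Prediction algorithms

**cRBH.** Two proteins are putative orthologs when each is the other's best
hit (bitscore, ties by lower E-value then smaller subject id) in the partner
species, among cross-species hits with E ≤ 1e-5 (default cutoff). The
optional filter `r ∈ [0,1]` (default: unset) retains a pair only if both

    min(L_X, L_Y) / max(L_X, L_Y) ≥ r
    aln_length    / max(L_X, L_Y) ≥ r

where L are full sequence lengths (taken from the FASTA records, not from
hit coordinates) and `aln_length` comes from the best hit in the direction
smaller-id → larger-id, a deterministic single source. Either deficiency —
length mismatch or poor alignment coverage — triggers removal, which makes
the retained set weakly shrinking in `r` and `r = 0` equivalent to no
filter.

**cRSD.** For each gene and target species, the top `top_n` hits (default 3;
"a small number" is all the method requires) are globally re-aligned and the
candidate with the smallest evolutionary distance is selected; a pair is
emitted when the relation is reciprocal. The distance is the closed-form
gamma-rates-corrected Poisson estimator on the mismatch fraction `p` of
aligned residue columns (gap columns excluded so that `p < 1`):

    d = a · ((1 − p)^(−1/a) − 1),    a > 0 (default 0.5)

which is strictly increasing in `p`, decreasing in the shape `a`, and tends
to the Poisson correction −ln(1 − p) as a → ∞. The original RSD fits a
maximum-likelihood distance under an empirical substitution matrix; the
closed form is used here as a dependency-free variant that preserves the
role and default of the shape parameter. Note that for a fixed alignment
the distance is monotone in `p`, so the choice of `a` changes reported
support values far more than it changes which pairs are selected; `a`
matters when candidate alignments differ.

**Clustering.** Pairs form an undirected graph (no within-species edges —
both methods predict strictly single-copy cross-species groups and cannot
represent inparalogs). A connected component containing two or more genes of
one species is in conflict, and that species is dropped from the component.
Because removal can split components — creating or dissolving further
conflicts — dropping is iterated to a fixed point: each pass removes every
currently conflicted species simultaneously, then components are recomputed.
The simultaneous pass makes the result independent of processing order
(one-at-a-time removal with intermediate re-componenting is genuinely
order-dependent, which is why it is not used); termination is guaranteed
because the vertex set strictly shrinks. Components with ≥ 2 genes become
orthogroups, named after their smallest member id. A brute-force
re-implementation of the same fixed point (plain set operations,
permutation-checked removal within each pass) serves as a test oracle on
graphs of ≤ 12 genes.

A subtle consequence of the conflict rule, kept as a regression test:
*removing* an edge can *enlarge* a group, because the deletion may split a
component in a way that dissolves a conflict and restores a previously
dropped species. Monotone shrinkage under edge deletion holds only on
conflict-free graphs.

## Similarity layer

Real datasets enter as 12-column tabular hits from any external search
tool. For synthetic data the internal scorer computes exact global
(Needleman–Wunsch/Gotoh) alignments under BLOSUM62 with affine gaps
(open 11, extend 1), scaled to bits with fixed Karlin–Altschul-style
constants (λ = 0.267, K = 0.041) and converted to a synthetic E-value
E = m·n·2^(−bitscore) from the full sequence lengths. Only the score
ordering and the cutoff semantics matter downstream. Per (query, target
species) the top `prescreen_top` (default 5) subjects under an exact
ungapped global score are rescored with the affine aligner, and hits above
`evalue_emit_max` (default 1e-3) are not emitted — the behaviour of a search
tool's report threshold, with a margin above the 1e-5 analysis cutoff.
Candidate pairs are pooled over both directions and mirrored on emission, so
bitscores are exactly symmetric. The scorer performs no heuristic seeding
and is not a replacement for a real search tool on real proteomes.

## Evaluation pipeline

Each curated pillar is split into two gold subgroups (pre-WGD genes + one
track); an empty track still yields the pre-WGD-only subgroup. A test group
is matched to the subgroup sharing the most genes, with at most one subgroup
per pillar eligible (the better of the two), ties resolved by the larger
shared fraction of the test group and then the smaller subgroup id — the
tie-breaks are not substantive, only deterministic. Groups sharing ≥ 2 genes
are *defined*; over defined groups, shared genes count as TP and unshared
test genes as FP, while FN is global: gold genes absent from *every* test
group (a gold gene found in the wrong group is an FP there, never an FN, so
nothing is double-counted). Defined counts are extrapolated by
ρ = undefined genes / defined genes (genes counted from test-group sizes,
so ρ is computable from predictions alone), giving tTP = TP(1+ρ) etc., and
tTN = N − tTP − tFP − tFN with N the full proteome size. Metrics follow the
formulas in the module docstring; a metric whose denominator is zero is
reported as undefined rather than coerced.

Stratified evaluation re-runs the entire pipeline (gold universe, matching,
extrapolation) restricted to pillars of one loss class, with N kept global.
The species-subset sweep re-runs inference itself on hits restricted to each
k-subset, rebuilds subgroups restricted to those species (pillars left with
fewer than two genes are dropped), and sets N to the subset's proteome size.
Parameter sweeps evaluate a grid (e.g. r over {unset, 0.1, …, 0.9} or the
gamma shape over its range) and emit ROC coordinates (1 − specificity,
sensitivity).

**Limitation — extrapolation in small strata.** ρ-extrapolation assumes
defined groups are representative and the gene universe is much larger than
the gold set. In a small stratum most predictions can be undefined (ρ ≫ 1)
while FN is large, and the extrapolated totals can exceed N, i.e. tTN < 0.
`ConfusionTotals` treats that as a hard error (the invariant tTN ≥ 0 is part
of the contract); the CLI's `--by-class` mode reports such strata as skipped.
At realistic scale (tens of thousands of genes against a few thousand gold
groups) the situation does not arise.

## Simulator

Study conditions are held in `SimConfig`: number of pillars (default 100),
class proportions (default uniform over 0–IV; empirical class frequencies
of curated yeast pillars are not published, so a neutral mixture is used),
sequence length 300, `branch_divergence` 0.2 expected substitutions/site on
every terminal branch, `wgd_divergence` 0.3 between the two track ancestors,
50 unrelated background genes per species, and a seed. Ancestral proteins
are uniform over the 20 residues; evolution is a Poisson substitution
process (Poisson(L·t) events, each replacing a uniform site with one of the
other 19 residues), so the expected observed mismatch fraction after
divergence t is p(t) = (19/20)(1 − e^(−20t/19)) — a closed form the tests
use to check the distance estimator. Loss patterns are drawn uniformly among
the patterns consistent with the sampled class, and the generated pattern is
re-classified as a consistency assertion. No indels, rate heterogeneity,
gene conversion or horizontal transfer are simulated; homologous pairs
therefore align end-to-end, which is exactly what makes mismatch counting
closed-form. Passing tests consequently show algorithmic correctness under
clean divergence, not robustness to the alignment ambiguity, domain shuffling
or annotation noise of real proteomes.

Background genes are i.i.d. random sequences; they exercise the true-negative
term, which would otherwise be degenerate. With `wgd_divergence = 0` the two
tracks are statistically unidentifiable; the pipeline is required to run
(robustness case) but track assignment is arbitrary there.

## Numerical and design choices

* Total orderings everywhere randomness could leak in: best-hit ties by
  (bitscore, E-value, subject id); RSD candidate ties by smaller gene id;
  group ids from smallest member; sorted file output. Two runs with the same
  seed produce byte-identical artifacts.
* Minimum group size 2: a single gene is not a group, and matching needs two
  shared genes anyway.
* Saturated alignments (no identical columns, p ≥ 1) get infinite RSD
  distance and can never be nearest.
* The r filter's inputs (full lengths from FASTA, alignment length from the
  stored best hit) make it reproducible from the hit table alone, with no
  re-alignment.
* All simulation sizes used by the test-suite and the acceptance script
  (200-pillar recovery runs; 40-pillar paired trap runs over 5–10 seeds)
  were chosen as the package's standard desk-scale study conditions; they
  are large enough that the recovery and trap effects are far from their
  decision thresholds.

## Known limitations

* cRBH/cRSD cannot represent inparalogs by construction; on class-0/I/II
  pillars the conflict rule drops whole species, which depresses sensitivity
  — the expected behaviour of single-copy methods on duplicate-rich groups,
  and the evaluation measures exactly that.
* The internal scorer's E-values are synthetic; real analyses should import
  hits from a real search tool.
* The closed-form RSD distance is a variant of the original ML fit (above).
* Extrapolated totals can violate tTN ≥ 0 in small strata (above).
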