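# Methods

This note documents the statistical models behind `sporesort`, the
assumptions they make, the defaults and why, and what the synthetic-data
generators do and do not emulate.

## Relatedness and the sorting test

In a mixing experiment, two clones (one fluorescently labelled) are mixed,
starved, and allowed to form fruiting bodies; each body is scored for
labelled and unlabelled spores. For a body with labelled fraction
`p` and unlabelled fraction `q = 1 − p`, within-body relatedness is

    r = p² + q²,

the probability that two spores drawn at random from the body are
clonemates (each clone is taken as fully related to itself and unrelated
to the other). `r` ranges from 0.5 (complete mixing at a 50:50 input
ratio) to 1 (complete sorting). Relatedness is computed per fruiting body
and averaged with equal weight per body — not per spore — so large bodies
do not dominate; the standard error is the sample standard deviation
(n−1 denominator) over √n, reported as undefined for a single body.

Sorting is detected through dispersion, not location: under sorting the
labelled proportion across experimental bodies is pushed toward 0 and 1,
inflating its variance relative to the two same-clone controls. The test
statistic is

    F = mean(var(exp₁), var(exp₂)) / mean(var(ctrl₁), var(ctrl₂)),

with sample variances (n−1). Significance comes from pooling all
per-body proportions across the four treatments and dealing them back
out without replacement into the four treatments with observed sizes
preserved, 5000 times by default; the one-tailed upper p-value uses the
add-one convention p = (1 + #{F* ≥ F_obs}) / (1 + resamples), so p is
never 0 and is bounded below by 1/(resamples + 1). Resamples whose
shuffled control variance is exactly zero are counted as maximally
extreme (F* = ∞ ≥ F_obs). Proportions, not raw counts, are permuted.

## The spore-count generator

Control bodies draw labelled spores Binomial(n, 0.5). Experimental
bodies first draw a latent labelled fraction q ~ Beta(a, a), then
Binomial(n, q). The single shape parameter `a` ("sorting strength")
spans the whole behavioural range: a → ∞ is pure mixing (the null),
a → 0 is hard sorting (every body clonal), and intermediate values give
overdispersed mixtures. The mixture has a closed-form expected observed
relatedness,

    E[r̂] = 1 − (1 − 1/n) · a / (2a + 1),

(from E[p̂q̂] = (1 − 1/n)·E[pq] and E[pq] = a/(2(2a+1)) for Beta(a, a)),
which is what the parameter-recovery tests check at a ∈ {0.2, 1, 5},
n ∈ {50, 200}, 500 bodies per treatment.

What the generator does not emulate: unequal input ratios between the
two clones, labelling toxicity or label leakage, body-size variation
correlated with composition, and spatial correlation among bodies from
one plate. Passing tests therefore demonstrate the statistics' operating
characteristics under a clean exchangeable null and a Beta-binomial
alternative, not robustness to those artefacts.

Default design for simulation studies: 30 bodies per treatment of 100
spores each — a plausible bench-scale counting effort, and large enough
that the variance-ratio null distribution is well populated.

## Distances

All distances are substitutions per site on aligned sequences.
Site-pattern counting distinguishes the two transition classes (A↔G,
C↔T) from transversions and uses pairwise deletion by default (a column
counts for a pair iff both records have an unambiguous base there);
complete deletion restricts to columns valid in every record. Pairwise
deletion is the default because ragged chromatogram ends otherwise
discard most of the alignment.

* p-distance: mismatches / usable sites.
* JC69: d = −(3/4)·ln(1 − 4p/3).
* TN93: the standard closed form with observed base frequencies and the
  two transition classes.

A log argument ≤ 0 raises a saturation error; in matrices the entry is
stored as NaN with a `saturated` flag, never as infinity.

The composite-likelihood matrix (`mcl_distances`) shares parameters
across pairs the way composite-likelihood distance estimators do: base
frequencies and the two transition/transversion rate ratios (κ₁, κ₂)
are estimated once by inverting the TN93 closed form at the site-pattern
counts pooled over **all** pairs; each pair's distance is then the 1-D
maximum-likelihood branch length for its own counts under those shared
parameters (bounded scalar optimisation of the multinomial likelihood of
the pattern categories). For a two-sequence input the pooled counts are
the pair's own counts and the estimate reproduces the plain TN93 closed
form — the anchor the tests verify to 1e-6. The exact iteration schedule
of legacy all-pair-simultaneous implementations is not reproduced; the
pooled-parameter scheme is the package's defined estimator.

Haplotype collapsing: `strict` groups byte-identical sequences;
`ignore_gapN` (default) treats two sequences as the same haplotype when
they agree at every column where both are unambiguous, so trailing gaps
and chromatogram Ns do not split haplotypes. That relation is not
transitive, so haplotypes are its connected components (single linkage);
a heavily ambiguous sequence can therefore bridge two otherwise distinct
haplotypes — it is reported as one class rather than being arbitrarily
assigned. The representative sequence is that of the lexicographically
smallest member id, making output deterministic.

## AMOVA

Two-level analysis of molecular variance (among/within populations) in
the standard sums-of-squared-distances form given at the top of
`sporesort/amova.py`, with δ² = pairwise nucleotide difference counts by
default (the usual choice for haplotypic data); `squared_input` squares a
supplied model-corrected matrix instead. Negative variance components are
clamped to zero and flagged, and Φ_ST = σ²_among/(σ²_among + σ²_within).
The permutation test permutes individuals across populations (sizes
preserved), compares unclamped Φ* against the unclamped observed Φ, and
uses the add-one p-value; the default 1023 permutations matches common
practice for this analysis.

A structural caveat worth knowing: when every individual's variants are
private (no shared polymorphism), pairwise difference counts are additive
(d_ij = m_i + m_j) and SSD_among is identically zero for *every*
labelling — the permutation distribution of Φ is degenerate and the test
is maximally conservative. Real populations share segregating sites, so
the null-calibration simulations use a dense-polymorphism configuration
(2 populations × 6 individuals, 60 sites, per-site within probability
0.3) where the statistic is non-degenerate; measured there, the mean null
p is ≈ 0.5 and the rejection rate at α = 0.05 is nominal.

Small fixed designs also bound the attainable p: with 2 + 2 individuals
only 6 distinct labelings exist and 2 of them are maximally extreme, so
p cannot go below ≈ 1/3 no matter how many permutations are drawn. The
significance checks therefore use 10 + 10 individuals, where an extreme
Φ is genuinely significant.

## The sequence generator

A star phylogeny: a uniform-random ancestral sequence; each population
ancestor is mutated per site with probability `p_between` (uniform choice
among the three alternative bases); each individual is mutated from its
population ancestor with probability `p_within`. `p_between = 0` implies
zero expected among-population variance. There is no coalescent within
populations, no rate heterogeneity among sites, no indels — the generator
exists to drive the distance and AMOVA code with known structure, not to
model ribosomal DNA evolution.

## Mating compatibility

Replicated pairwise macrocyst assays are aggregated per unordered pair by
strict majority; exact ties are reported as ambiguous and excluded from
the graph (a majority rule is undefined for even splits, and ties are the
natural flag for contamination or occasional selfing). Self-pairings are
aggregated but stored as selfing records — selfing is not evidence about
mating types and would confound bipartiteness — and appear only in the
diagonal of the group table (controlled by `include_self`, default on).

Mating types are inferred by 2-colouring each connected component of the
compatibility graph. A consistent colouring means the data are compatible
with exactly two mating types; clones with no positive mating are
reported unassignable rather than forced into a part. For a violating
component a shortest odd cycle is reported (found by BFS from each
vertex: a same-level edge closes an odd cycle through the last common
ancestor of the two endpoint paths) — length 3 is the "triad" pattern of
three mutually compatible clones, the signature of more than two types or
bisexual clones. Completeness is the fraction of tested cross-part pairs
that actually mated.

The mating generator plants k latent types, tests every unordered pair
(selfs included) a configurable number of replicate times, and flips
replicate outcomes at configurable false-positive/negative rates; with
zero noise and k = 2 the aggregated graph is complete bipartite by
construction.

## Numerical and design choices

* All sample variances/SDs use the n−1 denominator.
* All Monte-Carlo procedures take an explicit integer seed (numpy
  `default_rng`) and record it in their outputs; identical seed ⇒
  byte-identical output.
* Permutation comparisons use a 1e-12 slack on ≥ to make ties robust to
  floating-point noise.
* Distance text output is written to 6 d.p. (matrices) with group
  summaries at 3 d.p., matching the precision at which such distances
  are conventionally reported.
* Simulation sizes in the test-suite (200 replicate datasets for error
  rates; 500 bodies for parameter recovery; 199 permutations in the
  AMOVA null calibration, where p-values are valid at any permutation
  count) were chosen to give Monte-Carlo error comfortably inside the
  asserted bands while keeping the suite quick to run.

## Known limitations

* `ignore_gapN` single-linkage collapsing is order-independent but can
  chain through low-information sequences; use `strict` when exactness
  matters.
* The composite-likelihood distance assumes stationary base composition
  shared across the set; strongly heterogeneous composition violates the
  pooling.
* The AMOVA is strictly two-level (among/within populations); no
  hierarchical groups-of-populations level and no pairwise-population
  Φ matrix.
* Mating-type inference reports bipartiteness of the observed graph; it
  does not estimate the number of types beyond two, and sparse testing
  can make a non-bipartite truth look bipartite.
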