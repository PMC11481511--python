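# Methods

`paraphage` delimits operational phage species among prophages predicted
from bacterial genome assemblies, and relates those species to the host
population's structure (MLST lineages), geography and co-residence
patterns. This note records the models, the parameters that matter, the
numerical choices, and what the synthetic test bed does and does not show.

## Quality filters

Prophage predictions arrive as a tab-delimited table (CheckV-style columns:
prophage id, source genome, contig, 1-based inclusive coordinates,
completeness %). A prediction is retained iff its completeness is
*strictly greater than* 50% and its contig is *at least* 30,000 bp — the
two comparisons deliberately differ in strictness, matching the wording
the thresholds come from ("more than half complete", "at least 30 kb").
Contigs with several prophage signals are resolved by a deterministic rule:
signals whose coordinate intervals overlap are merged (union of
coordinates, maximum completeness), disjoint signals stay separate, and
every touched contig is reported. The curation this replaces was manual;
the merge-on-overlap rule is the only automatable reading, and the report
preserves auditability.

## Fragment ANI

Average nucleotide identity follows the fragment-based (ANIb-style)
convention:

* the query is cut into consecutive non-overlapping **1,020 bp** fragments;
  a final shorter fragment is kept only if ≥ 100 bp;
* each fragment is locally aligned to the whole subject under an affine
  scoring contract: match **+1**, mismatch **−1**, gap of length *L* costs
  **−5 − L** (open −5, extend −1);
* a fragment is retained iff its best alignment spans ≥ **70%** of the
  fragment with ≥ **30%** identity (identity = matches / alignment columns,
  gaps included);
* pair identity is the alignment-length-weighted mean identity over
  retained fragments; coverage is the fraction of query bases inside
  retained alignments. **A pair with no retained fragment scores identity
  0 and coverage 0** — zero, not missing. This convention is what makes a
  pooled mean of intra-genome ANI interpretable: unalignable co-resident
  prophages drag the mean toward 0 rather than being dropped.

The matrix pair (identity, coverage; rows = query) is asymmetric because
coverage is query-referenced and fragment boundaries differ between the
two directions.

### Aligner backends

Two implementations share one scoring and tie-breaking contract
(tie order: diagonal > gap-in-subject-consuming > gap-in-query-consuming >
terminate; gap runs prefer opening; first best cell in row-major order):

* `exact` — exhaustive Smith–Waterman over the full dynamic-programming
  matrix. Quadratic time and memory; the reference used in oracle tests
  and practical up to a few kb.
* `seeded` (default) — each fragment is located in the subject by exact
  16-mer matches (the subject index is complete; query k-mers are sampled
  every 4 positions, which at the identities this package resolves still
  leaves dozens of surviving seeds per fragment), and the same recurrences
  are run in a diagonal band of half-width 32 around the seed diagonals
  (seeds further than 300 diagonals from the median are discarded as
  chance repeats).

The banded result equals the exhaustive optimum whenever the optimal path
stays inside the band. At within-species divergences of a few percent the
expected net indel drift across a 1,020 bp fragment is ~1 bp, so a 32-
diagonal pad is generous; the test suite asserts exact equality of the two
backends on mutated pairs across divergences up to 5% with indels. The
seeded backend deliberately reports *no alignment* for fragments sharing
no 16-mer with the subject: for unrelated random sequences the exhaustive
aligner's best local alignment would in any case fail the 70%-span
retention rule, so the two backends agree on the retained-fragment
statistics; sequences in the 30–90% identity twilight zone with no intact
16-mers are outside this package's operating range and would need the
`exact` backend.

## Species delimitation

The two directed values per pair are symmetrized before thresholding.
Default: **mean of the two identities, minimum of the two coverages** —
conservative on coverage, so a short sequence embedded in a longer one
cannot chain two species together. (`mean-both` and `either-direction`
are available.) An edge joins two sequences iff symmetrized identity
≥ 95% **and** coverage ≥ 90% (a lenient 70/70 setting is used for
robustness checks; a `strict` flag switches ≥ to >; the inclusive reading
is the default because that is how the species definition is usually
stated operationally).

The graph is partitioned by **paracliques**: while edges remain, (i) find
an exact maximum clique (ties broken by the lexicographically smallest
sorted member list), (ii) repeatedly absorb the unassigned vertex adjacent
to at least ⌈g·|C|⌉ current members (g = 0.9 by default; smallest id
first), (iii) emit and remove. Leftover vertices become singleton species.
Species are then named `Ab_PS1…n` by decreasing size, ties by smallest
member id. Every step is deterministic. The glom threshold is computed as
`ceil(g*size − 1e−9)` to avoid binary-float artifacts (0.8·5 must be 4,
not 5). The exact maximum clique is obtained by enumerating maximal
cliques (networkx); at the near-clique component sizes this pipeline
produces that is fast, and a brute-force subset enumeration serves as the
oracle in tests.

Refinement (every strict cluster contained in one lenient cluster) and
"fewer clusters at lenient thresholds" are **not** theorems of paraclique
clustering on arbitrary matrices — a lenient maximum clique straddling two
strict clusters can split one of them. On communities whose between-species
identity is ~0 (the synthetic test bed, and empirically well-separated
collections) both properties hold, and that is where the package asserts
them.

## Host population structure

Sequence types follow the 7-locus Pasteur MLST scheme. The allelic
distance between two STs is the number of loci with differing alleles
(0–7); loci with a missing allele are excluded and reported. This is a
metric; a species' mean pairwise allelic distance over its STs
distinguishes "spread across closely related lineages" from genuinely
broad host range. Members lacking an ST (or country) are excluded from
range counts but reported, so "species assigned to STs" can be analysed
separately. Outlier fences for per-species country counts use **Tukey
hinges** (median-of-halves quartiles, the median belonging to both halves
at odd n) with fences at Q1 − 1.5·IQR and Q3 + 1.5·IQR; hinges rather than
interpolated quantiles because that is what "Tukey's method" names.

## Polylysogeny

Per-genome prophage counts (zero-count genomes included when metadata
lists them) are compared across host categories and STs with the
Kruskal–Wallis test. H is always tie-corrected (mid-ranks; divisor
1 − Σ(t³−t)/(N³−N)); p comes from χ² with k−1 df; all-identical samples
return H = 0, p = 1. Intra-genome ANI is reported **as a fraction in
[0, 1]** (symmetrized identity / 100) to keep per-genome distributions on
the scale on which "mean ≈ 0.04" reads naturally; the conversion happens
only at this module's boundary. The pooled mean/sd is over pairs, not over
per-genome means.

## Diversity

The species accumulation curve is incidence-based (site = genome) and
exact: E[Sₙ] = S − Σᵢ C(T−Tᵢ, n)/C(T, n), evaluated with log-gamma (stable
for thousands of sites). The standard deviation comes from the analytic
variance of the hypergeometric formulation, including the pairwise
covariance terms via joint absence probabilities; the confidence band is
±1.96 sd (the band construction was an open choice; a normal band on the
analytic sd is the simplest defensible one). An individual-based
"rarefaction" variant mapped to sites (richness rarefied to
m = n·N/T individuals) is available because site-based and
individual-based readings of a rarefaction curve are both defensible; the
site-based exact formula is the default. A Monte-Carlo sampler of random
site orderings is included purely as a cross-check oracle.

The two-sample KS statistic is the sup of |F_x − F_y| over the pooled
support; the p-value uses the limiting Kolmogorov distribution at
√(en)·D with en = n_x·n_y/(n_x+n_y) (the convention of R's asymptotic
two-sample test — note scipy's `asymp` mode uses the one-sample `kstwo`
distribution instead and gives slightly different p). An exact permutation
p (full enumeration) is available for pooled sizes ≤ 20 and anchors the
oracle tests.

## The synthetic community generator

The generator is the test bed for everything downstream, so its defaults
*are* the study conditions of the package's acceptance checks:

| parameter | default | rationale |
|---|---|---|
| species | 40 | desk-scale analogue of a ~1,000-species collection |
| singleton fraction | 0.72 | the empirical skew: most species are singletons |
| cosmopolitan species | sizes (25, 20) over (5, 4) STs | few, very large, broad-host-range species |
| mid species | 9 species of size 3–7, one ST each | the narrow-host-range majority |
| ancestor length | 30–60 kb | typical prophage scale; also what the contig filter implies |
| within-species divergence | 0.01 subs/site | well inside the ≥95% identity cutoff; an explicit modelling choice, not an empirical estimate |
| indels | rate 5·10⁻⁴/site, geometric mean 2, cap 10 | keeps within-species coverage above 90% |
| genomes / STs / countries | 80 / 10 / 8 | enough capacity for the largest species under superinfection exclusion |
| host mix | human .80 / animal .15 / plant .05 | human-dominated sampling with non-human minorities |

Ancestors are independent uniform-random sequences, *not* phylogenetically
related: this guarantees between-species identity far below every
threshold, which is exactly what makes truth recovery a valid acceptance
surface. Members are ancestor mutants; narrow species are placed in
distinct genomes of a single ST; cosmopolitan species are placed
round-robin across their configured STs, so the truth table covers exactly
the configured spread. Genomes inherit their ST's home country except for
a 5% travel rate — lineages, and therefore most species, are
geographically confined, while multi-ST species span several countries;
this confinement is required for the robustness property that the median
per-species country count is unchanged by excluding singletons.
Superinfection exclusion is honored by construction (no genome receives
two members of one species; toggleable); infeasible configurations (more
same-species members than genomes in the chosen STs) fail loudly naming
the species. Completeness is 100 and contigs are prophage + 5 kb flank;
sub-threshold rows can be injected to exercise the filters.

Deliberately *not* modelled: gene content, GC bias, recombination,
mosaicism, prediction false positives, phylogenetic relatedness among
species. Consequently, passing the recovery checks shows the pipeline is
correct and deterministic under clean species structure; it does **not**
show how real prophage collections behave near the 95/90 boundary, where
mosaicism and shared modules blur species edges.

## Problem sizes and determinism

Default-scale runs (≈120 prophages of 30–60 kb, ≈14,600 ordered ANI pairs)
complete in a few minutes on one core; oracle tests run on ≤5 kb pairs and
≤10-vertex graphs where exhaustive enumeration is feasible. One integer
seed drives every stochastic stage through a single `numpy` generator, so
identical configurations produce byte-identical outputs, including the
FASTA and all tables.

## Known limitations

* The paraclique variant (exact seed + glom growth, g = 0.9) follows the
  published paraclique literature; equivalence with any particular
  in-house implementation of the same idea cannot be asserted.
* The seeded aligner backend assumes homologous fragments share intact
  16-mers; use `backend="exact"` for divergent (< ~85% identity) pairs.
* The accumulation curve treats genomes as exchangeable sites; structured
  sampling (by lineage or country) is not modelled.
* Host categories are fixed to {human, animal, plant}; free-text detail is
  carried through but not analysed.
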