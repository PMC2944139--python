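# Methods

This note documents the model, the numerical choices, and the limits of
what the test suite shows. It states no number that the tests or
`scripts/acceptance.py` do not themselves compute.

## Metagene construction

Seed ortholog pairs (reciprocal best matches per genome pair) for
yeast–mouse and yeast–human are read from two-column TSVs. Genes are
grouped into connected components over the union of both pair sets (two
pairs sharing any gene merge), and each component containing at least one
yeast gene becomes one metagene; components without a yeast gene are
discarded with a logged count. The type — YMH, YM, YH — is the organism
span of the component, which makes the types mutually exclusive and every
metagene yeast-anchored. How membership should be decided from purely
pairwise tables is genuinely open; connected components are the minimal
rule that needs no extra inputs and reproduces mutual exclusivity. It can
create metagenes with more than one gene per organism (two yeast genes
sharing a mouse best match), which is why pair correlation averages over
member cross-products. Metagene ids are the `+`-joined sorted yeast gene
ids, stable under any input order.

## Expression preprocessing

The pipeline accepts already-normalized signal-intensity matrices;
platform normalization is upstream and out of scope.

* **Probe collapsing.** A probe mapping to exactly one gene is unique;
  a gene's signal is the mean of its unique probes. A gene with none
  falls back to the mean of its multi-mapping probes whose ids end in
  `_a`; a gene with no usable probe is dropped and counted.
* **Replicate averaging** then **prophase windowing**: columns with
  t_min − tol ≤ t ≤ t_max + tol are kept. The tolerance (default 0.5 time
  units) exists because sampling grids rarely align exactly with stage
  boundaries — e.g. an embryonic-ovary sample at 14.5 days against a
  window ending at day 14; without the tolerance such a study would keep
  only 2 points, and a 2-point Pearson correlation is always ±1, so fewer
  than 3 surviving timepoints is an error.
* **Low-expression filter.** Per gene, the maximal signal over the
  retained (prophase) window; the `floor(0.10·n)` genes with the smallest
  maxima are dropped. Ties at the cut break by gene-id sort order so the
  result is deterministic. Lowly expressed profiles are noise-dominated
  and would otherwise seed spurious correlations.
* **Abundance classes.** A gene is `high` iff its maximal prophase
  intensity is strictly above the median of those maxima over the *full*
  pre-filter gene set of the study; median-tied genes are `low` (so at
  most half the genes are `high`). Maxima are taken over the prophase
  window, not the full course. Labels are invariant under global monotone
  rescaling.

## Correlation, ranking, conservation P-value

Pearson correlation uses sample (n−1) standard deviations and requires
≥ 3 timepoints and non-zero variance; zero-variance genes are excluded
with a count. A metagene pair's correlation is the mean over all member
cross-products, computed for the whole pair set in one weighted matrix
product (`W C Wᵀ` with row weights 1/|members|), which is exact and keeps
the ~10⁵-pair tables fast.

Ranking is by signed r, descending: the method targets positive conserved
co-expression, and a `rank_by="abs"` flag exists for the alternative.
Ties receive the mean of their covered ranks (deterministic). The rank
ratio rank/total is Uniform(0, 1] under the null of independent ordering.

The conservation P-value of a pair with ascending ratios r₁ ≤ … ≤ r_n is
the probability that n sorted independent uniforms fall below those
bounds. It is evaluated in closed form by the recursion V₀ = 1,
V_k = Σ_{i=1..k} (−1)^{i−1} (V_{k−i}/i!) r_{n−k+1}^i, P = n!·V_n — exact,
O(n²) per pair, no quadrature — and validated against both the analytic
n = 2 form 2r₁r₂ − r₁² (to 1e−12) and a 10⁵-draw Monte-Carlo oracle
(within 3 standard errors). A pair must be rankable in *every* member
study of a network to be scored; the four-study network counts the two
mouse studies as separate dimensions (n = 4) because conservation here is
across studies/sexes, not genomes. No multiple-testing correction is
applied to pair P-values: ranking, not calibrated significance, is the
operative use, and the top-K (default 100) interface makes that explicit.
P-value ties in output tables break by pair id.

## Evaluation

* **Precision/coverage.** At depths of 100 pairs (configurable), distinct
  metagenes among the top-d pairs are collected; precision is the
  fraction containing ≥ 1 known gene of the evaluation organism
  (metagenes, not genes, are counted, and de-duplicated across pairs),
  coverage the number of distinct known genes recovered.
* **Permutation baselines** shuffle the *order* of the same pair list
  with a seeded generator (not endpoint rewiring — the null being tested
  is "ranking carries no information", and order shuffling yields the
  flat baseline curves expected of it).
* **Observed vs random.** The pooled test is Welch's unequal-variance
  two-sample t-test of the observed curve values against all trial
  values. A per-depth Welch test is impossible — the observed curve has
  exactly one value per depth — so the per-depth p reported is a
  one-sample t-test of the trial values against the observed value.
* **GO enrichment.** Hypergeometric upper tail p(x ≥ k) with t = genes in
  the network universe, n = universe genes annotated, m = query genes,
  k = annotated query genes, summed in log space (gammaln + logsumexp)
  and validated against exhaustive enumeration for t ≤ 12. Annotations
  are propagated to is_a ancestors before counting (standard GO practice;
  required for SLIM-style terms). Raw p-values are reported against
  α = 0.05; a Benjamini–Hochberg flag exists but is off by default.
* **Semantic similarity.** p(c) = fraction of corpus genes annotated to
  term c or any descendant (monotone toward the root, p(root) = 1); the
  pair score is −log10 of the minimal p(c) over shared ancestors
  (self-inclusive), 0 when only the root is shared. The p(c) corpus is
  the metagene universe (configurable); only is_a edges are traversed.
* **Overlap/abundance statistics** flag a metagene pair when any yeast
  member cross-product hits a pairwise relation (interactions) or shares
  a group id (complexes); node-level curves flag metagenes containing a
  property gene (essential). Multi-gene metagenes are `high` if any
  member is high — with ~1 gene per metagene per organism this is nearly
  always the singleton's label.

## Clustering route

Per-study correlation tables restricted to metagenes present in all
studies are merged by elementwise **minimum** — a pair is only as
conserved as its worst study — with diagonal 1. Dissimilarity is
d = 1 − r (option (1 − r)/2), clustered by average linkage. The branch
cut is a deliberate simplification of shape-adaptive dynamic tree
cutting: the number of clusters of size ≥ `min_cluster_size` (default 40)
is tracked along all merge heights, and the cut is placed at the *last*
height of the longest height interval over which that count is constant.
Maximizing the count instead provably selects arbitrarily high cuts where
loose background agglomerates masquerade as clusters and genuine modules
merge; the persistent-count rule keys on the observation that real
modules are stable over long height ranges. Cutting at the run's last
height lets late-merging members join their cluster. Members of
sub-threshold branches are labeled unassigned (module 0). A constant
matrix returns a single module with a warning.

When the clustering route is used to check recovery of planted modules,
it is run on windowed but *unfiltered* matrices and with
`min_cluster_size` equal to the planted module size (20): the bottom-10 %
abundance filter is a network-route noise control that can remove the
low-abundance half of a planted module whose latent profile peaks low in
one study, and a 10-gene remnant can never satisfy a 20-gene size floor.
The pipeline default for real data remains filter on, min size 40.

## Synthetic study conditions

The generator emulates the structure the method assumes, with defaults
that are the shipped study conditions:

| parameter | default | meaning |
|---|---|---|
| study grids | 5 / 4 / 3 / 13 points | yeast hours 0–4; mouse testis 6–14 dpp (duplicates); mouse ovary 11.5–14.5 dpc (duplicates); human ovary 9.1–18.1 weeks |
| n_metagenes | 500 | 1:1 ortholog-aligned gene triples |
| modules | 5 conserved + 3 single-study, size 20 | planted co-expression blocks |
| noise_sd | 0.25 | Gaussian noise relative to unit signal amplitude |
| abundance_levels | (10, 1000) | multiplicative low/high base, alternating by index |
| ortholog_coverage | 0.88 | background metagenes typed YMH (rest split YM/YH) |
| extra_genes_fraction | 0.15 | per-organism genes with no ortholog (enter medians/filters only) |

Each conserved module gets an independent smooth latent profile per study
(cubic spline through ≤ 4 uniform control points on the study grid,
normalized to unit peak amplitude); gene signal is
base·(1 + f(t) + ε), floored at 1 % of base. Conservation means
*within-study co-expression in every study*, not equal profile shapes
across studies. Single-study modules receive a profile in exactly one
study. The GO fixture is a 3-level is_a DAG whose "meiosis-like" leaf
annotates exactly the first conserved module (the planted known-gene
set); unrelated leaves annotate background genes only, because drawing
unrelated-term annotations from planted modules would make those terms
co-expression-enriched by construction. Interactions sample 30 % of
within-module yeast pairs; complexes coincide with conserved modules;
essential genes are 18 % of the genome plus 20 % of module genes. All
randomness derives from the single scenario seed through fixed-offset
substreams, so equal seeds give byte-identical written fixtures.

What the generator does **not** emulate: probe-level and batch noise,
platform intensity distributions, many-to-many orthology, cell-type
mixture, or missing values. Passing tests therefore show the machinery
is correct and the statistics behave as designed under the assumed
generative structure — not that the biological conclusions of any real
dataset are reproduced.

Two knock-on properties worth knowing. First, with a unit-*amplitude*
profile on a sparse grid a module can be nearly flat in one study (a
spline through similar control points), which weakens its within-study
correlation; at low noise this occasionally degrades clustering-route
recovery for one module at some seeds. Second, the low-abundance half of
a module whose profile peaks low in a study is legitimately caught by the
bottom-decile filter — the same behaviour the filter is designed to have
on real data.

## Pipeline and reproducibility

The file-driven pipeline (`meionet all --config config.yaml`) executes
orthology → preprocessing → correlation → scoring per network recipe →
evaluation (+ optional clustering), logs gene counts at every filtering
step (in = out + dropped, asserted), and writes a manifest with the seed
and SHA-256 digests of every input. All tables are written with fixed
float formatting; identical config + inputs give byte-identical outputs.

Problem sizes in the shipped checks: the default 500-metagene scenario
(~75 000–81 000 scored pairs per two-study network, 51 000 for the
four-study network), 100-trial permutation baselines, 10⁵-draw
Monte-Carlo validation of the order-statistics CDF, and exhaustive
hypergeometric enumeration up to t = 12.

## Known limitations

* The connected-component metagene rule is a documented stand-in for an
  unknown published procedure; with dense many-to-many orthology it can
  chain large components.
* The persistence branch cut approximates, but is not, dynamic tree cut;
  branch-shape information is ignored.
* Negative-correlation (anti-co-expression) analysis is out of scope
  (`rank_by="abs"` exists but is untested science).
* Per-study correlation significance is not assessed; only cross-study
  rank conservation is.
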