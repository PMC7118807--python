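# Methods

This note documents the models and procedures implemented in `netmods`,
the parameters that matter, the numerical choices, and what the synthetic
data can and cannot establish.

## Node weights from GWAS p-values

SNPs are assigned to a gene when they lie in the gene body or within a
symmetric flank (default 50,000 bp on each side, applied in genomic
coordinates regardless of strand — with equal flanks on both sides the
strand is irrelevant to the window). Gene-level p-values come from one of
two combiners: Šidák on the minimum, p = 1 − (1 − min pᵢ)^m, or Fisher's
method, X = −2 Σ ln pᵢ ~ χ²(2m). Both ignore linkage disequilibrium
between SNPs and therefore overstate significance for genes with many
correlated SNPs; they are honest summaries only under approximate SNP
independence. When an LD-aware gene test has already been run, its output
is loaded directly and the combiners are bypassed — that is the preferred
path. Combined p-values are clipped to [10⁻³⁰⁰, 1 − 10⁻¹⁶] before the
quantile transform so z = Φ⁻¹(1 − p) stays finite.

**Extreme-signal capping.** A handful of genome-wide-significant genes can
dominate every module the greedy search returns (their z outweighs any
neighborhood). The default rule floors every gene with
p < 0.05 / (number of scored genes) to the smallest p among the remaining
genes and flags it; a `drop` strategy removes such genes instead. The
threshold is user-overridable.

**Search substrate.** Network genes without a score are excluded from the
search (the search needs a weight for every node it may recruit; imputing
one would invent signal); scored genes absent from the network are simply
unreachable. Disconnected network components are kept — seeds there just
produce small modules.

## Dense module search

Module score: Z_m = Σ zᵢ / √k over the k member z-scores — the sum
normalized by its null standard deviation, so Z_m is comparable across
sizes under independent N(0,1) node scores. Every scored gene seeds one
search. Expansion is best-first, one gene per iteration: all genes within
shortest-path distance d (default 2) of the current members are scored
tentatively, the best is recruited if Z_{m+1} > Z_m·(1 + r) (default
r = 0.1), ties break to the lexicographically smallest symbol, and the
search stops when the best candidate fails the test. The procedure is
fully deterministic. `max_iter` (default 1000) guards pathological growth
and warns if hit.

Degenerate-score handling: the multiplicative rule inverts its sense for
Z_m ≤ 0, so the equivalent additive form Z_{m+1} > Z_m + |Z_m|·r is used
there; it coincides with the multiplicative rule for Z_m > 0 and demands
strict improvement at Z_m = 0.

Because a recruit may sit two hops from the module without its linker
gene, module connectivity holds in the d-step sense; the induced subgraph
may be disconnected for d ≥ 2. Post-hoc, every module satisfies the
local-maximality certificate — an exhaustive, cache-free rescan of the
d-neighborhood finds no candidate passing the acceptance rule — which the
test suite verifies against an independently coded step-by-step simulator.

Run-level normalization: Z_n = (Z_m − mean)/sd with the population sd over
all modules of the run. The top-k modules by Z_n (default k = 50, ties by
seed symbol) merge into the reported subnetwork; per-gene output includes
a nominal-significance flag (p < 0.05) and the subnetwork's nominal
fraction.

## Dual-dataset evaluation

Discovery modules are re-scored with the evaluation dataset's z-scores
over the same gene sets; the resulting Z_m_eval values are standardized
across the discovery modules (not a fresh evaluation-side search). A
module is consistent when its discovery Z_n reaches the 0.99 quantile of
the run (a "top modules" proxy) **and** its evaluation Z_n is at least
1.64 (one-sided normal 0.05). Both cuts are configurable; neither is
claimed to reproduce any particular published selection exactly. The
procedure is one-directional (discovery → evaluation); swapping roles is a
matter of swapping inputs. The Pearson correlation between discovery and
evaluation Z_m over modules is reported as a sanity check — near-zero or
negative correlation argues against trusting the direction chosen.

## Differential co-expression edge weights

Within-condition Pearson correlations r_case and r_control (clipped to
±0.999999 before atanh) feed the Fisher z statistic

z_raw = (atanh r_case − atanh r_control) / √(1/(n_case−3) + 1/(n_control−3)),

the standard two-sample test for comparing correlations; it requires at
least 4 samples per condition and is antisymmetric under label swap.
Because a gain and a loss of co-expression are equally interesting, the
search consumes w = |z_raw| standardized over edges (mean 0, sd 1) and
shifted so min w = 0. Edges touching a zero-variance gene are dropped with
a warning. Expression is assumed already normalized on the log2 scale; the
loader warns when per-sample medians spread more than 2 log2 units.
Differential expression is reported per gene as the difference of
condition means (log2FC) with Welch's two-sample t-test (robust to the
unequal variances expected at 7 vs 6 samples); flags mark p < 0.05 and
|log2FC| > 1 (strict).

## Edge-weighted module search

Seeds are edges, so every module has at least two genes (max_size default
10). The edge aggregate mirrors the node formula, Z_edge = Σ wⱼ / √m over
the m member edges, and the combined score is s = λ·Z_node + (1 − λ)·Z_edge
with λ ∈ [0, 1], default 0.5. An `auto` mode equalizes the channels'
spread — λ·sd(node increments) = (1 − λ)·sd(w) over all weighted edges —
and logs the chosen λ. Identical final gene sets are deduplicated keeping
the best score. With λ = 1 and zero weights the search reduces to the
node-only greedy rule started from gene pairs (verified in tests).

**Permutation significance.** For each observed module size k, n_perm
(default 1000, minimum 100) null modules are grown from uniformly random
seed edges by the *same best-first greedy rule*, forced to size k, and
scored with the observed weights; p_perm = (1 + #{null ≥ s}) / (n_perm+1).
The null is deliberately subjected to the same greedy optimization as the
observed modules: random un-optimized connected subgraphs score
systematically below any greedily grown module, so a random-subgraph null
declares essentially every module significant in signal and null data
alike and carries no information (we measured 100% pass rates in both
conditions on synthetic data). Against the greedy-matched null,
background modules land mid-distribution (drawing a module from the null
itself yields p ≈ 0.5 on average) while modules capturing genuine node or
edge signal remain in the tail. The null conditions on size, uses the
observed weight tables without refitting, and is deterministic given the
seed.

## Enrichment

Hypergeometric upper tail P(X ≥ overlap) with population |universe|,
successes |set ∩ universe|, draws |query ∩ universe|. Sets with
universe-restricted size outside [10, 500] are excluded before testing and
from the Bonferroni denominator; significance is p_adj ≤ 0.05. Only
over-representation is tested. The universe defaults to the union of
collection members; passing the scored-gene list is recommended since it
is the set the search could actually have selected. Redundancy reduction
clusters significant sets by Jaccard similarity with affinity propagation
(damping 0.9, preference = median similarity, ≤1000 iterations), falling
back to greedy best-p-first clustering at Jaccard ≥ 0.5 when affinity
propagation does not converge; one exemplar (lowest p) is flagged per
cluster. Venn-partition counts are reported for 2–3 gene sets.

## Synthetic data

The generator emulates the structure of the real inputs, not their
content:

* **Network** — preferential attachment: a complete clique on attach+1
  founders (attach = 3), each later node linking to `attach` distinct
  existing nodes with probability ∝ degree. Connected by construction,
  heavy-tailed degrees like a curated interactome; edge count is exactly
  C(attach+1, 2) + attach·(n − attach − 1).
* **Dual GWAS** — one connected planted set chosen by random walk (which is
  degree-biased, so plants often touch hubs — as disease modules on real
  interactomes do); planted genes draw z ~ N(node_effect, noise_sd)
  independently per dataset, background z ~ N(0, 1), p = 1 − Φ(z). Two
  datasets share the plant but not the noise, which is exactly the
  property dual evaluation exploits.
* **Expression** — planted genes follow an equicorrelated multivariate
  normal (r_case within cases, r_control within controls; positive
  definiteness requires r > −1/(k−1)), background genes independent
  N(0, 1); an optional mean shift in cases produces differential
  expression. Defaults are 7 cases vs 6 controls. A probe-splitting
  wrapper (1–3 probes per gene, N(0, 0.1) offsets) exercises probe
  collapsing.

Not modeled: linkage disequilibrium, allele frequencies, platform and
batch effects, co-expression outside the planted set. Passing tests
demonstrate that the machinery recovers planted structure under clean
noise assumptions; they say nothing about robustness to LD-induced score
correlation or expression confounding.

All generators are deterministic given their seed, and the recorded
ground truth (planted genes, effects, parameters, seeds) suffices to
regenerate the data byte-identically.

## Problem sizes used in the checks

The end-to-end checks run at a 500-gene network with an 8-gene plant
(node effect 3.5, three replicate seeds) for node-signal recovery and dual
consistency; a 400-gene network with node effect 2.0, correlation shift
0.8 vs 0.0, and 500 permutation draws per module size for the
edge-weighted comparison; 1000 label permutations of a 40-gene null
expression dataset for edge-weight calibration; and 200 random graphs of
up to 30 nodes for oracle equivalence of the greedy search. These sizes
give stable statistics while keeping a full run around a minute on one
CPU.

## Known limitations

* The SNP combiners are LD-naive stand-ins; use precomputed gene p-values
  from an LD-aware test when available.
* Greedy search finds locally, not globally, dense modules; modules from
  nearby seeds overlap heavily and are reported as found (deduplication
  only in the edge-weighted variant, which collapses identical gene sets).
* The consistency thresholds (top 1%, Z ≥ 1.64) are reasonable defaults,
  not canonical values; selection is sensitive to them when few modules
  carry shared signal.
* Permutation p-values are conditional on the observed weight tables; they
  rank modules against chance subnetworks, they are not genome-wide error
  rates.
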