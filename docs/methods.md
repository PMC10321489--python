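# Methods

This note documents the models and procedures implemented in `paramotif`,
the defaults chosen where the underlying conventions leave room, and what
the synthetic-data generator does and does not emulate.

## Motif enumeration

All five motif types are licensed by a duplicate gene pair: an instance
exists only if its defining pair is present in the paralog-pair table.
Instances are identified by the unordered licensing pair plus the partner
set, so the two orderings of a pair never double-count, and all members of
an instance must be distinct genes — autoregulation and within-pair edges
(T1→T2) do not create V or lambda partners, and a direct p1–p2 interaction
is not a PPI V. A pair with a gene absent from the network contributes
zero motifs silently, since networks cover only part of the paranome.

Definitions:

- **V**: regulators T1, T2 (the pair) share a target g ∉ {T1, T2}.
- **PPI V**: proteins p1, p2 share an interaction partner x ∉ {p1, p2}.
- **lambda**: targets g1, g2 share a regulator T ∉ {g1, g2}.
- **delta**: default reading — a V whose regulators additionally share a
  PPI edge. The alternative reading (a lambda whose targets share a PPI
  edge) is available via `find_delta(..., topology="lambda_plus_target_ppi")`;
  only the predicate differs, the enumeration is shared. On identical
  inputs, delta instances are a strict subset of V (or lambda) instances.
- **bifan**: a regulator pair with shared-target set S contributes one
  bifan per unordered target pair from S. By default the target pair must
  itself be in the paralog table (`require_target_paralogy=True`), which
  matches how bifans are used in enrichment contrasts; the weaker
  definition (any target pair, C(|S|,2) per regulator pair) is a flag.
  A bifan is stratified by its regulator pair's mode and age group; the
  target pair's mode is recorded on the instance, and disagreement between
  the two pairs is flagged `mixed`. Counting (`count_only`) uses the
  closed form or a filtered pair count without materializing instances.

Counts are stratified by (motif type, duplication mode, age group), with
the stratum taken from the licensing pair's current table entry, so age
groups assigned after enumeration take effect at counting time.

## Null model and Z-scores

Null networks are produced by node-label permutation: the graph structure
is fixed and labels are shuffled, preserving every in-, out- and
undirected degree sequence exactly. Labels permute within role strata —
regulator-role nodes (out-degree ≥ 1 in the GRN), pure targets, and
PPI-only nodes — which preserves the bipartite role structure that
inference-derived GRNs have. One shared gene→gene relabeling per
permutation is applied to both networks (delta motifs span both; an
independent relabeling of the PPI network is available and implemented by
cycle-restriction of a second within-strata permutation to the PPI node
set).

Rather than rebuilding relabeled networks, the ensemble loop composes the
inverse permutation with the pair endpoints: counting motifs for (a, b) on
the relabeled network equals counting for (σ⁻¹a, σ⁻¹b) on the original.
The equivalence is asserted against explicit relabeling in the test suite.
One integer seed expands into per-permutation child seeds
(`numpy.random.SeedSequence.spawn`), so ensembles are reproducible and
could be parallelized without changing results.

Z = (observed − null mean)/null sd per stratum (sample sd, 1000
permutations by default); Z ≥ 2 is called significant; a degenerate null
(sd = 0) reports Z as NA rather than ±∞. Held-out calibration (a null
draw scored against the rest of the ensemble) has |mean Z| < 0.2 in the
acceptance suite.

## Ks peaks and age groups

Ks-peak detection fits a univariate Gaussian mixture by
expectation–maximization with a **user-fixed** number of components —
mixture order selection tends to over-split Ks distributions, so the
component count is an explicit input, as is standard when peaks are
matched to known polyploidy events. Defaults: Ks values outside
(0, 5.0] are excluded (saturation makes larger Ks unreliable); 10
restarts (first quantile-anchored, the rest seeded draws), convergence at
log-likelihood improvement < 1e−6, at most 500 iterations, variance
floored at (1e−4)²; the best converged restart wins. The EM loop is
implemented directly so the log-likelihood trajectory is exposed and its
monotone non-decrease asserted on every fit; the test suite cross-checks
recovered parameters against an independent mixture implementation.

An age group is the interval mean ± 2σ around a peak (floored at 0),
peaks indexed youngest-first. A pair inside exactly one interval gets
that group; inside several, the smallest standardized distance
|Ks − mean|/σ decides, ties to the younger peak (the tie-break is this
package's rule; it is deterministic and logged per pair only through the
resulting table). Pairs outside all intervals, or lacking Ks, are
`unassigned`. Assignment is idempotent.

## Michaelis–Menten divergence

Ka saturates with Ks, so Ka-vs-Ks scatter is fitted with
Ka = Vmax·Ks/(Km + Ks) by unweighted nonlinear least squares
(positivity-bounded Levenberg–Marquardt/TRF via `scipy.optimize.curve_fit`,
initialization Vmax₀ = max Ka, Km₀ = median Ks, tolerances 1e−10).
Vmax is the divergence asymptote, Km the half-saturation Ks, and Vmax/Km
the initial (linear-regime) divergence rate; the linear limit is checked
against an origin-constrained OLS slope in the tests. "Interacting" pairs
default to pairs whose proteins interact directly **or** share at least
one PPI partner; `direct_only` restricts to direct interactions. At least
20 points with finite Ka and Ks are required; all-equal Ks is rejected as
degenerate.

## Topology

The scale-free-topology fit partitions degrees ≥ 1 into 10 equal-width
bins on raw k, drops empty bins, and regresses log10(frequency) on
log10(mean k) by OLS; R² and the (signed) slope are reported, and fewer
than 3 non-empty bins (e.g. regular graphs) is a degenerate fit with
R² = NA. Equal-width raw-k binning follows the convention of the widely
used scale-free-fit-index procedure; the bin count is configurable.

GRN filtering ranks edges by weight descending (ties broken by canonical
regulator/target order for determinism), forms 20 nested subnetworks —
step i holds the top ⌈i/20·|E|⌉ edges, step 20 the full graph — scores
each subnetwork's total-degree sequence, and keeps the largest subnetwork
with R² > 0.75. Both step count and threshold are parameters; failure to
pass at any step raises an error carrying the full diagnostics table.

Sørensen–Dice similarity uses partner sets that exclude the pair's own
two genes, so S measures shared third-party partners; |A|+|B| = 0 gives
S = NA. In GRNs, `role_mode="auto"` compares regulator pairs by their
target sets and any pair involving a pure target by regulator sets.
Degree comparisons use out-degree for regulators, in-degree for pure
targets, undirected degree in PPIs; WGD vs SSD member genes are compared
by two-sided Mann–Whitney U with rank-biserial r = 1 − 2U/(n₁n₂).

## Enrichment

Term enrichment is Fisher's exact test per term (default alternative
"greater") over a user-supplied background, Benjamini–Hochberg adjusted
across tested terms, with terms annotated in fewer than 2 background
genes skipped to avoid vacuous singleton tests. The duplication-mode
membership test builds one 2×2 table (WGD-derived vs not) × (in network
vs not); genes in both a WGD and an SSD pair count as WGD-derived, with a
flag to drop them instead.

## Synthetic data

The generator emulates the statistical shape of the real inputs, not
their biology:

- GRNs grow as directed bipartite graphs with a fixed in-degree per
  target and preferential (or uniform) regulator attachment; preferential
  attachment yields the heavy-tailed regulator degrees that scale-free
  fitting expects. `hub_weights` correlates edge weights with regulator
  connectivity so that high-weight quantiles are hub-dominated, giving
  the quantile filter meaningful structure. PPIs are Erdős–Rényi.
- Planted motifs use fresh nodes only, trading realism for exact count
  ground truth: each planted instance is node-disjoint from the
  background and from every other planted instance, so finder counts on
  the planted part equal the recorded expectation exactly (including the
  implied secondary motifs: a delta is also a V; a bifan contributes two
  V and, through its paralogous target pair, two lambda).
- Duplicate pairs draw Ks from a two-component truncated Gaussian mixture
  (defaults 0.15/0.05 and 1.10/0.20, weights 0.6/0.4 — a recent and an
  ancient duplication wave on the Ks scale) and Ka from the
  Michaelis–Menten curve (Vmax 0.5, Km 0.4, noise sd 0.02) with the WGD
  group's Vmax scaled by 0.6 to plant the slower-divergence contrast.
- The full-study preset composes these and additionally gives WGD pairs
  4 shared + 2 private PPI partners vs 1 shared + 2 private for SSD
  pairs (planting the similarity contrast), plants more V motifs on
  recent-WGD than ancient-WGD pairs (30 vs 8), samples background pairs
  degree-stratified (regulators with regulators, targets with targets) so
  null Z-scores stay calibrated, and labels WGD-pair genes
  `dosage_sensitive` at 70% vs 10% for everyone else.

What passing tests on this data do **not** show: robustness to the noise
structure of real inference scores, to incomplete or biased PPI coverage,
to Ks estimation error and alignment artifacts, or to paralog
misclassification — none of which the generator models. Sizes in the
suite (hundreds of nodes, ~200 pairs, 100–1000 permutations) are chosen
as the smallest scales at which every planted effect is detected
decisively; all generators scale to larger runs unchanged.

## Known limitations

- Node-label permutation preserves degrees exactly but also preserves the
  full graph structure; it does not sample the configuration model, and
  the package deliberately offers no edge-rewiring null.
- The EM fit is univariate and unconstrained beyond a variance floor;
  heavily overlapping components will trade weight freely, and the
  component count is never selected automatically.
- The delta topology follows the V-plus-regulator-interaction reading by
  default; analyses that intend the lambda reading must switch the
  predicate explicitly.
- Enrichment treats terms independently (no ontology graph propagation).
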