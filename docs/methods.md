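# Methods

This note documents the models and procedures implemented in `gutnetdys`,
the choices made where the design was genuinely open, and what the
synthetic benchmark does and does not demonstrate about real data.

## Study design and data model

The pipeline analyses a caged-bee exposure experiment: 4 clothianidin
doses (0, 0.1, 1, 10 ppb in 50% sucrose syrup), 5 cages of 200 newly
emerged bees per dose, 28 days, daily mortality and syringe-weight
records, weekly removals of 20 bees per cage for sampling. Gut microbiota
is profiled per gut section (midgut, ileum, rectum) at day 7 via 16S rRNA
*transcript* amplicons: per-taxon counts are read as relative
transcriptional **activity**, not cell abundance. The resulting activity
table is 120 samples (3 sections × 4 doses × 5 cages × 2 replicates;
10 per section × dose condition) by however many ASVs survive upstream
denoising — the pipeline starts from a finished ASV count table and never
touches reads.

`ActivityTable` is a validated samples × taxa `DataFrame` wrapper (counts
stored as float; integrality enforced at ingestion of raw tables and by
estimators that require it). Metadata, survival and feeding ledgers are
validated `DataFrame`s. TSV orientation is fixed samples-in-rows; a
transposed table is corrected only when its column ids match a known
sample list, otherwise it is an error — silent transposition being the
classic microbiome-pipeline failure.

## Taxonomic assignment

An ASV with a best BLAST hit (against a 16S reference, tabular `-outfmt
6` with `staxids`) **strictly above 98% identity** inherits that hit's
full lineage. Otherwise the lineages of the top 50 hits by bitscore are
reconciled by an unweighted lowest common ancestor: the deepest of the
seven ranks (superkingdom → species) at which all hits agree. "Above 98%"
is read strictly (a 98.0% hit goes to the LCA branch); the threshold and
the top-N are configurable. Missing intermediate ranks inherit the parent
name with an `unclassified_` prefix so rank-walks never gap; identity
weighting of the LCA would be a possible extension but is not
implemented.

## Co-abundance networks

Per condition (section × dose), in order:

1. **Genus aggregation.** ASV counts are summed by the genus of their
   lineage; ASVs resolved only above genus form
   `unassigned_<rank>_<name>` buckets (they are *not* merged into any
   genus); fully unassigned ASVs pool under `unassigned`. Column order is
   descending total activity with lexicographic ties, so outputs are
   deterministic.
2. **Occurrence filter.** A genus is kept iff present (count > 0) in
   strictly more than 0.7·N of the condition's N samples — at the design
   size N = 10 that is ≥ 8 of 10. Subsets with fewer than 4 samples are
   rejected (a rank correlation on 3 points is meaningless).
3. **Spearman screen.** All retained-genus pairs, Spearman ρ with
   average-rank ties on per-sample **relative** activity; two-sided p
   from t = ρ·√((n−2)/(1−ρ²)) with n−2 df (|ρ| = 1 → p = 0). Spearman is
   rank-based, so the relative-vs-raw choice only matters when sequencing
   depths differ between samples; proportions make the screen invariant
   to any per-sample depth rescaling by construction. Genera constant
   across the subset yield undefined correlations; their pairs are
   removed from the testing family (and from the Bonferroni multiplier m)
   with a log line.
4. **Dual correction and edge rule.** Benjamini–Hochberg and Bonferroni
   (p·m, capped at 1) are both computed over the g(g−1)/2 family. An edge
   requires |ρ| ≥ 0.4 AND BH-p < 0.05 AND Bonferroni-p < 0.05. The
   Bonferroni clause dominates the BH clause, making the conjunction
   redundant — it is enforced anyway because the screening recipe this
   pipeline reproduces applies both; `bonferroni=False` relaxes to
   FDR-only. Edge sign is the sign of ρ; retained genera without edges
   stay as degree-0 nodes.

A full design yields 12 networks plus a summary of node and signed-edge
counts per condition. Exports: SIF (`source pp|pn target`, isolated nodes
as bare lines), GraphML with node activity/class and edge ρ/sign, and an
edge TSV that round-trips the signed edge set exactly.

The estimator is plain pairwise Spearman — deliberately, because that is
the procedure under study. Compositionality-aware alternatives
(SparCC/SPIEC-EASI) are out of scope; the compositional closure effects
this implies are quantified below.

## Topology and network comparison

Cytoscape NetworkAnalyzer conventions, sign-agnostic:
degree DG; neighborhood connectivity NC = mean degree of neighbors;
closeness centrality CC = 1/mean(shortest-path length to nodes reachable
from the node), computed per connected component without Wasserman–Faust
size normalisation (networkx `closeness_centrality(wf_improved=False)`
is exactly this). Degree-0 nodes take NC = CC = 0 by convention. Network
pairs are compared per metric with a two-sided Mann–Whitney U (normal
approximation with tie correction), direction reported as difference of
medians; the comparison grid applies no multiplicity correction by
default (a BH option exists in the diversity chain, not here). The test
choice is a design decision — the comparison is nonparametric to match
the rest of the pipeline's nonparametric stance.

## Dysbiosis signature

For an exposed condition versus its section control: node and signed-edge
tallies; per genus, correlation partners gained (neighbors only in the
exposed network) and lost (only in control), with both partner-count and
edge-count views; activity direction from the change in mean relative
activity with a ±10% stability band ("stable" is otherwise undefined —
the band is explicit and configurable); taxon classes: **core** =
membership in a configurable list (default Lactobacillus,
Bifidobacterium, Gilliamella, Snodgrassella, Frischella), **low
activity** = contributing < 0.01% of the condition's summed activity AND
present in fewer than 0.3·N samples (both clauses required; < 3 of 10 at
design size), else **noncore**. **Keystone** flags mark nodes in the top
quartile of *both* DG and NC among nonzero-degree nodes — an explicit,
testable operationalisation of a term usually used narratively. Note a
star's hub is *not* keystone under this rule (its NC is minimal); hubs
embedded in well-connected neighborhoods are.

## Alpha diversity and differential activity

Chao1 (bias-corrected: S_obs + F1(F1−1)/(2(F2+1)), via scikit-bio) and
Shannon in nats, computed on raw per-sample ASV counts without
rarefaction; per-sample depths are reported alongside so comparability
can be judged. Group comparisons: Kruskal–Wallis (tie-corrected), Dunn's
pairwise z on pooled ranks with the standard tie correction, BH across
the pairwise family. Dose comparisons can pool gut sections or stratify
by section.

Differential activity is a deliberately simple, fully specified statistic
rather than a negative-binomial GLM: within the two-arm (dose vs control,
one section) subset, counts are normalised by median-of-ratios size
factors (geometric means over all-positive taxa; "poscounts" fallback
over positive entries when no taxon is positive everywhere; factors
normalised to geometric mean 1); the effect size is
log2((mean_exposed + c)/(mean_control + c)) with pseudocount c = 0.5;
p per ASV from the two-sided Wilcoxon rank-sum on normalised counts, BH
across the subset's ASVs, significance flagged at adjusted p < 0.05.
Consequences worth knowing: the statistic is exactly antisymmetric under
arm swap, depth-invariant up to < 0.02 log2 units at counts ≥ 50, and at
n = 10 per arm the rank-sum p rarely survives BH across ~30 ASVs — effect
sizes carry most of the information at this design size. No shrinkage or
dispersion modelling is attempted.

## Survival and feeding

Kaplan–Meier product-limit estimation runs directly on the aggregated
per-cage per-day ledger (at-risk, deaths, censored): S(t) = Π(1 −
dᵢ/nᵢ) over event days, censored bees leaving the risk set after their
day. Weekly 20-bee samplings are treated as right-censoring at the
sampling day (how else removed bees could enter a survival analysis is
not well defined). Median survival is the first day with S ≤ 0.5. Group
comparison is the standard 1-df log-rank with hypergeometric variance;
proportional-hazards regression is intentionally not reimplemented — the
ledger is exportable for off-the-shelf survival packages. lifelines is
used in the test suite as an independent oracle for both estimators,
never as the implementation.

Feeding rate per cage-day = syrup mass consumed / mean(bees alive at
t−1, bees alive at t); group-vs-control comparison defaults to the
rank-sum over cage-day values, with a signed-rank variant paired by day
(averaging cages within groups) — the pairing unit for a signed-rank
test on this design is ambiguous, so both are provided and the unpaired
one is the default. A per-day Kruskal–Wallis across groups is also
emitted.

## Synthetic data generator

The generator reproduces the study conditions so every stage is testable
offline: 120 samples in the full factorial design (all at day 7), a
4000-bee survival cohort, and feeding trajectories.

**Activity model.** A Gaussian copula over genera: latent standard
normals with a planted correlation matrix are mapped through per-genus
lognormal marginals exp(μ(section) + ln2·Δ(dose) + σ_g·z). Spearman's ρ
is invariant under monotone marginals, so a planted rank correlation
survives to the absolute activities exactly; a Spearman target ρ_s is
planted as latent Pearson 2·sin(π·ρ_s/6). Genus activities are split
into 1–4 ASVs by Dirichlet(5) weights fixed per genus, scaled to a
negative-binomial depth (mean 25 000, dispersion 5 — the study reports no
per-sample depths, so these are fixed, arbitrary defaults) and rounded.
Planted matrices that are not positive definite are repaired to the
nearest correlation matrix; if the repair moves any target by more than
0.05 (Spearman units) the config is rejected with advice to weaken the
targets. Rare genera (Ralstonia, Devosia, Leifsonia, Flavobacterium,
Moraxella) are injected in at most 2 of 10 samples per condition at
~5·10⁻⁵ relative activity, below the low-activity threshold.

Section profiles make the rectum Lactobacillus/Bifidobacterium-dominated,
the ileum Gilliamella/Snodgrassella-dominated and the midgut mixed; dose
effects deplete Frischella (−1 log2 at every nonzero dose), raise
Bifidobacterium (+0.5), and move Gilliamella and Lactobacillus
non-monotonically — the qualitative exposure phenotype. Default planted
edges give the control more positive couplings than exposed conditions,
with negative couplings appearing under exposure.

**Compositional closure, quantified.** Downstream screens correlate
*proportions*, and dividing by a varying per-sample total perturbs ranks.
The perturbation grows with the share-weighted variance of the community
log-total: planting +0.95 between two genera holding 50% and 18% of
activity leaves only ≈ +0.68 in the proportions, and a −0.95 pair in a
six-genus even community retains only ≈ −0.58 (measured at n = 10⁵).
Strongly negative rank correlations between proportions are
mathematically unreachable unless the planted genera are small relative
to a stable total. The defaults therefore (a) plant edges among mid-tier
genera (each a few percent of activity) and (b) model the dominant core
genera with a smaller log-sd (0.4) than the dynamic planted genera (1.2)
— biologically sensible (large stable core populations, volatile minor
taxa) and sufficient for planted +0.95/−0.9 to survive closure at ≈
+0.95/−0.83.

**Survival/feeding model.** Daily deaths are binomial at a constant
per-dose hazard; defaults 0.0424, 0.0341, 0.0315, 0.0310 per day for
0.1, 1, 10 and 0 ppb encode the inverse dose–mortality ordering with
analytic medians near days 16, 20, 22 and 22. Weekly samplings are
recorded as censoring. Feeding: cage mass = per-bee intake(dose) ×
mean(alive before, after) + N(0, 0.3 g) truncated at zero; default
intakes 0.050/0.052/0.060/0.048 g·bee⁻¹·day⁻¹ put the 1 ppb group
highest. With noise off, `feeding_rate` inverts the model exactly — an
end-to-end identity used as a test.

**Determinism.** All randomness flows from one integer seed through
named `numpy SeedSequence` spawns (ASV structure, activity with one
child per condition, survival, feeding), so equal seed + config gives
byte-identical outputs; the pipeline manifest records SHA-256 digests of
every artifact to make this checkable.

## Edge-recovery benchmark

Recovery of a planted correlation by the full generator → aggregation →
filter → screen → edge-rule path is a power question with a closed form:
at n = 10 and a Bonferroni family of m pairs, the t-approximate detection
threshold is the ρ solving p(ρ) = 0.05/m — about |ρ| ≈ 0.87 for the full
ten-genus community (m = 45), which a true 0.95 clears only ~78% of the
time; no implementation can do better at that family size. The package
therefore defines `recovery_benchmark_config`: one condition of 10
samples over a stable dominant background genus (85% of activity, log-sd
0.05, keeping the closure denominator rank-neutral) plus six dynamic test
genera carrying three disjoint planted pairs at ±0.95. Seven genera give
m = 21 and a threshold of ≈ 0.82, where measured recovery is ≈ 85–87%
pooled over 20 seeds with each edge individually ≥ 85%. The null variant
(nothing planted) yields a post-Bonferroni false-edge rate around 0.2–1%
of pairs, far inside the 5% control. These numbers are what
`scripts/acceptance.py` recomputes.

## What the synthetic benchmark does not show

The generator emulates the *statistical* structure the pipeline is
sensitive to, not real gut biology: no true compositional interactions
(cross-feeding, exclusion), no spatial structure within sections, no
cage effects or replicate correlation (samples within a condition are
i.i.d.), no taxonomic mis-assignment noise, no chimeras or contamination,
and hazards are time-constant where real cage mortality is not. Passing
tests demonstrate the estimators and filters behave as specified under
known ground truth — they do not certify biological conclusions on real
data, where unmodelled covariance (especially cage effects, which halve
the effective n of a 2-replicates-per-cage design) will widen every
uncertainty.

## Numerical conventions

TSV outputs use fixed 6-significant-digit float formatting for
cross-platform byte-stability. Perfect monotone pairs snap to ρ = ±1,
p = 0 (within 1e−12 of the tie-free bound). Identical constant arms in
the rank-sum test report p = 1 rather than NaN. Quantile cut-offs for
keystone flags use pandas' default linear interpolation. Sample size
floors: correlations need ≥ 4 samples and ≥ 2 genera; differential
activity ≥ 3 per arm; network comparisons ≥ 3 nodes; Dunn ≥ 2 values per
group. The sequencing-depth floor is 1000 counts (no failed libraries
are simulated).
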