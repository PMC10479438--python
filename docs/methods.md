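# Methods

This note documents the statistical procedures implemented in `fibermeta`,
the synthetic-data model used to validate them, the numerical conventions,
and the design choices made where the procedure left room.

## Analysis stages

### Iterated rarefaction and alpha diversity

Rarefaction draws, for each sample, a multivariate hypergeometric
subsample of exactly `depth` reads (sampling without replacement), repeated
for `iterations` draws (default 1000). Samples whose total is below the
depth are dropped once, with a warning. The default depth is the minimum
sample total of the table — the largest depth that retains every sample.
Diversity indices are computed per draw and averaged per sample; averaging
after the index (rather than computing the index of an averaged table)
keeps the estimate unbiased under subsampling.

Shannon entropy is reported in nats (−Σ pᵢ ln pᵢ) and Simpson as the
Gini–Simpson form 1 − Σ pᵢ², the defaults of the common community-ecology
toolkits. The paired test uses, per subject, the earliest pre-intervention
and latest post-intervention sample, a two-sided paired *t* on the
per-subject differences, and reports both the raw difference of the
subject-mean index and the percent change relative to the pre mean. If the
differences have exactly zero variance around a nonzero mean the test is
degenerate; p = 0 is reported with a warning. If the pre mean index is 0
the percent change is NaN (flagged), since the ratio form is undefined.

### Distance-based variance partitioning (PERMANOVA)

Pairwise dissimilarity is Bray–Curtis, BC(x,y) = Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ),
computed per rarefaction draw on square-root transformed counts (the sqrt
damps dominant taxa) and averaged element-wise across draws. The partition
follows the McArdle–Anderson distance-based linear model: with
G = −½ J D² J the Gower-centered squared-distance matrix and H_k the
orthogonal projector onto the design columns of terms 1..k (plus
intercept), term k's sum of squares is tr(H_k G) − tr(H_{k−1} G)
(sequential, Type-I), the residual is tr(G) − tr(H_K G), and
pseudo-F_k = (SS_k/df_k)/(SS_res/df_res). Terms are fitted subject first,
then the pre/post factor, so the intervention term is the variance
explained *after* removing subject differences. Significance uses free
(unrestricted) permutation of sample labels — equivalently simultaneous
row/column permutation of the fixed averaged distance matrix — with
p = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm), default 999 permutations
(p floor 1/1000). The averaged matrix is not re-averaged inside
permutations. Free permutation is approximately calibrated here because
the design is balanced (each subject contributes one pre and one post
sample); the type-I error of the fiber term is verified empirically in the
test suite (0.02–0.08 band at 200 null replicates). Degrees of freedom are
computed from the realized rank of the design, so an aliased term is
reported with df 0 rather than silently absorbing variance.

### Differential abundance and cross-study consensus

Counts are filtered per study (OTU total ≥ 10, present in ≥ 3 samples,
then prevalence ≥ 50% of samples; boundary values are kept) and normalized
by median-of-ratios size factors: the reference profile is the geometric
mean of each OTU across samples over OTUs positive in every sample, and a
sample's factor is the median ratio of its counts to the reference (a +1
table-wide pseudocount is the fallback when no OTU is shared by all
samples). The effect estimate is the plug-in
log₂((mean_post + c)/(mean_pre + c)) over normalized phase means with
pseudocount c = 0.5, which bounds the ratio when a phase mean is zero.

Significance comes from a subject-paired sign-flip permutation test: per
subject, the difference of phase-mean normalized abundance Δ; observed
statistic T = mean over subjects of Δ; null by randomly negating each
subject's Δ (two-sided on |T|). With fewer than 5 paired subjects all 2ⁿ
sign patterns are enumerated exactly and p = #{|T| ≥ |T_obs|}/2ⁿ (the
identity pattern is included, so the floor is 1/2ⁿ — 1/8 at n = 3).
Benjamini–Hochberg adjustment runs within each study across OTUs;
significance is p_adj < 0.05, and |log₂FC| > 0.58 (a 1.5-fold change)
flags a large effect. This deliberately replaces a negative-binomial
shrinkage estimator with a fully specified, oracle-testable procedure that
preserves the same decision rule; the shrinkage machinery itself is not
what this pipeline studies.

The consensus stage keeps "widespread" OTUs that survived filtering in at
least 3 studies, averages their per-study log₂FCs without weights, calls
the direction by the sign of the mean (an exact zero is classed negative
and flagged ambiguous), and marks |mean| > 1 as a top responder. No
further multiplicity correction is applied across the consensus, matching
a procedure that thresholds per study and then averages.

### Phylogenetic conservation (consenTRAIT)

Trees come either from data — uncorrected p-distance with pairwise
deletion of N/gap positions on an aligned 16S fragment, then Saitou–Nei
neighbor joining — or from the simulator. The p-distance (no substitution
model correction) is deliberate: τ_D is interpreted on a raw 16S
sequence-dissimilarity scale, and NJ on such distances preserves that
scale. NJ uses the Q-criterion Q(i,j) = (n−2)d(i,j) − Σd(i,·) − Σd(j,·),
standard limb lengths, negative limb estimates clamped to zero with the
deficit moved to the sibling edge, row-major tie-breaking, and roots the
result at the final three-way join (trifurcating root, conventional for
NJ); a midpoint-rooting helper is provided and recorded when used. On
additive matrices NJ is exact, which the tests exploit as an oracle.

consenTRAIT with cutoff 0.9: traversing from the root, a node is a
consensus clade when ≥ 90% of its descendant tips carry state 1 and no
ancestor already qualifies (maximal disjoint clades). A clade's depth is
the mean path length from its ancestral node to its descendant tips — a
distance-scale quantity, not a height above the root. Trait-positive tips
outside every clade are singletons and contribute half their terminal
branch length when `count_singletons` (the original convention; exposed as
a flag because implementations differ and published τ_D values do not
disambiguate it). τ_D is the mean over clade depths (plus singletons).
Positive and negative responders are analyzed in two separate runs, each
binarizing one direction to 1. Significance shuffles trait labels across
tips (preserving the number of 1s), one-sided for deeper-than-random
conservation. The reported value applies to the rooted tree as given;
rerooting across a clade boundary can change clade membership.

The Mantel test (Spearman by default) correlates the off-diagonal entries
of two cophenetic matrices over the same tip set, with a one-sided
permutation null that relabels one matrix; it serves as the tree-agreement
check between alternative reconstructions.

### Corpus summaries

`summarize_registry` uses the even-n median convention (mean of the
central pair) and the sample (n−1) standard deviation; both conventions
are required to reproduce the published corpus footers from their 12
per-study durations. `summarize_meta` computes per-column means over all
rows and over the rows flagged significant for that column, plus counts of
significant flags and of interventions whose alpha diversity decreased
under at least one metric. Display rounding is 1 decimal for percentages
and 3 decimals for τ_D; raw values are retained in JSON. The bundled
tables normalize the source's free-text alpha annotations to
(direction, significant, metrics) triples, documented in
`src/fibermeta/data/README.md`.

## The synthetic-data model

`simulate_collection` generates, per study: a Bernoulli(occupancy = 0.7)
subset of the 200-OTU pool (so OTU sharing between studies is incomplete);
a per-study log-normal species-abundance profile a_o (σ_SAD = 1.5); per
subject, baseline log abundances a_o + N(0, σ_subject²); per sample, added
N(0, σ_noise²); post samples shift responder OTUs by ±β·ln 2 before the
softmax renormalization; counts are multinomial at a log-normal depth
(median 8000 reads, σ = 0.25). One pre and one post sample per subject.
Responder OTUs are whole clades planted on a pure-birth (Yule) tree with
exponential branch lengths rescaled to mean root-to-tip depth 0.10 (the
magnitude of genus-level 16S trees): disjoint clades whose mean
ancestor-to-tip depth is within ±30% of the target τ are selected until
the requested tip fraction (default 5% positive, 5% negative) is covered.

The `paperlike` preset (8 studies × 20 subjects) fixes
σ_subject = 1.0 and σ_noise = 0.65, calibrated so the PERMANOVA subject
term lands at ≈ 0.80 of compositional variance and the intervention term
in the low single-digit percent range — the regime the multi-study corpus
exhibits — with a planted effect of β = 1 log₂ unit at conservation depth
τ = 0.02. Because the positive and negative responder sets carry similar
mass, the post-shift renormalization roughly cancels and the marginal
log₂FC estimator recovers β without a compositional offset.

What the generator does *not* emulate: overdispersed (Dirichlet-
multinomial) count noise, varying study designs and depths, multiple
intermediate timepoints, taxonomic annotation, primer/region differences,
or per-study heterogeneity in effect size (no published estimates exist to
calibrate it). Multinomial noise was chosen because it keeps the
subject/intervention variance fractions analytically tunable; an
overdispersion mechanism can be layered on by widening σ_noise. Passing
tests on this generator demonstrate the estimators recover planted
structure under idealized noise, not that they are robust to every
artifact of real amplicon data.

A note on alpha diversity in the simulation: a planted effect changes
diversity only through dominance. A 2-fold shift on rare clades barely
moves Shannon/Simpson; the consistent diversity *decline* seen in real
fiber interventions emerges in the simulation only when responders bloom
to dominance (e.g. β = 4 on 10% of taxa, the configuration the test suite
uses), consistent with blooms of fiber-degrading genera driving the real
pattern.

## Numerical conventions and problem sizes

- All randomness flows through `numpy.random.default_rng(seed)`; each
  pipeline stage derives its own sub-seed, so stages are independently
  reproducible and all outputs are byte-identical across reruns.
- Permutation p-values use the (1 + exceedances)/(1 + permutations)
  estimator except the exhaustive sign-flip enumeration, which divides by
  2ⁿ including the identity.
- Projection matrices use a rank-revealing QR; design rank, not nominal
  column counts, sets the degrees of freedom.
- Test and validation runs use scaled-down Monte Carlo sizes chosen to
  keep the whole suite fast while leaving each check's statistical
  resolution ample: 5–25 rarefaction draws where the assertion does not
  depend on averaging precision, 99–999 permutations, 200 replicates for
  type-I-error bands (±0.03 around 0.05), 50 for the null FDR bound, 20
  seeds for variance-fraction recovery, 10 per target depth for τ_D
  recovery. The library defaults remain 1000 iterations / 999–1000
  permutations.

## Known limitations

- Sequential (Type-I) sums of squares make the fiber R² depend on the
  subject-first term order; the order is the analysis's point (intervention
  effect after subject differences) but is configurable in the generic
  `sequential_permanova`.
- Free permutation ignores the within-subject pairing; restricted
  (within-subject) permutation schemes are out of scope.
- The sign-flip test assumes the pre/post design is paired by subject;
  studies with replicate samples per phase are averaged per subject first.
- consenTRAIT results are reported for the rooted tree as given; NJ trees
  are arbitrarily rooted and a different rooting can change clade
  boundaries near the root.
- p-distances are uncorrected; saturation at deep divergences compresses
  τ_D for deeply conserved traits.
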