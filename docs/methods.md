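# Methods

This note documents the statistical models, the synthetic-data
generator, the numerical choices and the known limitations of
`moadecon`. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Differential expression

**Model.** Expression is consumed on the log2 scale. Samples are first
quantile-normalised (every column receives the row-wise mean of the
per-column sorted values; tied values share the mean of their would-be
quantiles via average-rank interpolation). Per gene, an ordinary
least-squares cell-means model is fitted over the treatment × DIV
factorial, with plate included as a fixed covariate whenever the design
has more than one plate level. The reported effects are the within-DIV
treatment contrasts (compound − vehicle at each DIV).

Plate is always modelled as a *fixed* effect. A random-plate (mixed)
model would be preferred when plate variance is detected, but for
balanced designs the fixed-effect fit gives identical contrast estimates
and a deterministic, solver-free implementation; the choice is recorded
in the fit metadata.

**Within-gene FWER.** The three contrasts per gene form the multiplicity
family. Single-step max-|t| adjustment: adjusted p of contrast *j* is
P(max over the family of |T| ≥ |t_j|) under the joint null multivariate
*t* implied by the shared contrast correlation and residual df,
estimated from Monte-Carlo draws (default 20,000, seeded and logged; a
warning is recorded below 1,000). The draw is shared across genes
because the family structure is identical, and adjusted p is floored at
the raw p. A family of one contrast is returned unadjusted. A
studentized-range (Tukey) statistic would assume all pairwise
comparisons of one factor; max-|t| handles the general contrast family
and coincides with it for balanced two-level contrasts.

**Across-gene resolution (p\*).** Per gene take the minimum FWER p;
BH-adjust the minima across genes; p\* is the largest minimum among
genes with q < 0.05; a contrast is significant iff its FWER p ≤ p\*.
The boundary is deliberately inclusive: the gene that defines p\* is
itself FDR-significant, so excluding it (strict <) would contradict its
own selection. If no gene passes FDR, p\* is undefined and nothing is
significant. DEG selection applies |log2FC| ≥ 1.5 and adjusted
p ≤ 0.05, both boundaries inclusive.

## Identifier mapping

Expansion first, aggregation second, in one pass: a source gene with
several orthologs contributes one row per target; several source genes
sharing a target are combined by the arithmetic mean of log2FC *and* of
the p-value. Averaging p-values is statistically improper — it is kept
because it is the convention this pipeline reproduces; `combine_p=
"fisher"` switches to Fisher's combination. Unmapped ids are dropped
and counted in the returned report. When a source gene both expands and
shares a target with another source gene, the expanded copy enters the
target's average like any other row (a consequence of the single-pass
order; no canonical behaviour exists for this corner).

## Enrichment and overlap statistics

Over-representation is the one-sided hypergeometric upper tail
P(X ≥ k) with the background set to every measured gene; gene sets are
intersected with the background before testing; BH is applied within
each collection (collections are analysis runs, adjusted separately).
Only enrichment (not depletion) is tested. An optional Jaccard ≥ 0.9
merge collapses near-duplicate sets for readability (off by default).

The overlap coefficient between two experiments' significant-pathway
sets is |A∩B| / min(|A|,|B|), reported to two decimals; it is undefined
for an empty input and then reported as 0 with an explicit flag.

Disease association: the supplied disease lists are unioned, intersected
with the background, and tested two-sided by Fisher's exact test on the
2×2 table; the sample odds ratio uses a Haldane 0.5 correction only when
a cell is zero. Two-sided is the default because the direction of
association is not assumed.

## TF activity and discretisation

Gene statistic x_g = log2FC if p ≤ 0.05 else 0 (the significance gate);
raw score of TF *t* = Σ_g w_{t,g} x_g over its measured regulon targets
(w = regulon signs). The NES standardises the raw score against
`n_perm` (default 1,000) permutations of gene labels. Regulons with no
measured target are omitted with a log entry; fewer than 3 measured
targets flags low confidence. Discretisation to {−1, 0, +1} at
|NES| ≥ 1.96 mirrors the two-sided 5% convention used throughout; the
threshold is configurable. The NES is exactly invariant to positive
rescaling of all gene statistics (raw score, null mean and null sd all
scale linearly). The enrichment statistic used by published
regulon-activity tools is not reproduced and equivalence is not claimed;
this scorer consumes any (tf, target, sign) table.

## Causal reasoning

Predictions: breadth-first shortest paths from the hypothesis (protein,
assumed sign σ) up to Δ; a node's predicted state is σ × the product of
edge signs along a shortest path; equal-length shortest paths that
disagree give 0 (ambiguous), and ambiguous nodes propagate both signs
onward — this matches enumeration of all shortest paths because every
prefix of a shortest path is itself shortest. The hypothesis node is
excluded from its own predictions.

Scoring: over measured nodes, prediction–observation agreement counts
+1, disagreement −1 (score = n_correct − n_incorrect); nodes predicted
ambiguous with a nonzero observation are tallied separately. The
p-value is the fraction of permutations of the *observed multiset across
all measured nodes* (zero states included) with score ≥ observed. The
zeros matter: restricting the null to the nonzero support would give
p = 1 whenever the explained observations all share one sign. The null
is enumerated exactly for ≤ 8 measured nodes (deterministic tests),
otherwise Monte-Carlo sampled; within a ranking run the permutation
block is drawn once and shared, since the null depends only on the
observed multiset.

Ranking tests both signs of every protein at each Δ ∈ {1..5}, sorted by
score, then p, then protein id. Consensus nodes are the (protein, sign)
hypotheses significant (p ≤ 0.05) at the greatest number of path
lengths, ties retained. The consensus subnetwork is the union over
consensus nodes of *all* shortest paths (≤ Δ_max) to each observation
whose predicted and observed states agree; its edges always come from
the source network. Pooling across setups counts, per protein, the
number of setups whose hypothesis set contains it (signs recorded
alongside); the pooled set keeps proteins at frequency ≥ ⌈n_setups/2⌉
by default — the frequency rule is qualitative ("most frequently
recovered"), so the default is a stated choice, not a derived one.

## Ligand-based target prediction

Fingerprints are radius-2 Morgan/circular, hashed to 2048 bits
(ECFP4-equivalent); synthetic corpora may instead carry generated
bit-vectors, tagged `synthetic`. Tanimoto is |a∩b|/|a∪b| with the
both-empty case defined as 0.

The reference pipeline this mirrors uses pre-trained random-forest
classifiers per (target, potency threshold); rebuilding them requires a
licensed-scale training corpus. This module instead exposes the same
interface over a transparent predictor: per (target, threshold T), the k
(default 5) most similar corpus compounds with data for that target vote
with weight = Tanimoto similarity; probability = Σ T_i·y_i / Σ T_i with
y_i = (activity ≤ T μM). "Active at T" means potency at least T, so
thresholds tighten from 100 down to 0.1 μM. Similarity ties break by
compound id; duplicated corpus rows are collapsed per compound, making
predictions invariant to corpus duplication. Probability equivalence to
any specific pre-trained stack is not claimed; nearest-neighbour
similarities are directly reproducible.

Applicability domain: the query statistic is its mean similarity to the
k nearest training compounds; the reference distribution is the same
statistic for each training compound, leave-self-out; the percentile is
100 × the fraction of reference values ≤ the query statistic. The
percentile definition used by the reference pipeline is cited to
external work and not restated there; this leave-self-out form is this
package's documented stand-in.

Unbound Cmax = total Cmax × fraction unbound, both consumed as inputs.

## Evidence integration

A process map (process → associated genes and pathway ids) is an
explicit, versioned input — the assignment of pathways and targets to
higher-level processes is a curation step, not a computation. A process
gains the target stream when a prediction with probability ≥ 0.3 and
applicability percentile ≥ 50 maps to it, the regulator stream when a
pooled regulator maps, and the pathway stream when a significantly
enriched pathway maps. Processes are ranked by stream count, then total
evidence items, then label; zero-stream processes are excluded from the
headline, and an empty headline is reported as "no consensus".
Literature plausibility and phenotype concordance are human judgments
and remain free-text annotations, not computations.

## Synthetic-data generator

The generator emulates the data model of a two-treatment × three-
timepoint (DIV 3/7/14) factorial experiment with 3 replicates per cell
on 2 plates:

- **Network**: out-degree 1 + Poisson(mean − 1) per node (expectation =
  `mean_out_degree`, minimum 1), uniform random targets, each edge
  inhibitory with probability `inhibitory_fraction` (default 0.3). No
  self-loops; no opposite-sign parallel edges.
- **Planting**: genes within `depth` (default 2: regulator → TF →
  transcript) of a planted regulator receive treatment shifts of sign =
  regulator sign × shortest-path sign product; sign-ambiguous genes are
  left unperturbed; the regulator itself is not transcriptionally
  shifted (hypotheses are protein-activity states). Effect magnitude is
  `effect_size` (default 2.0 log2 units) scaled linearly by DIV/14, so
  differential expression accumulates with time in culture — the
  qualitative pattern of DEG counts growing over treatment duration; no
  quantitative match to any particular experiment is attempted.
- **Noise**: per-(gene, plate) intercepts with sd `plate_sd` (default
  0.1) and Gaussian residuals with sd `noise_sd` (default 0.3). The
  emulated study does not publish replicate-level variance or plate
  effect sizes, so these are free parameters chosen as plausible
  log2-scale magnitudes, set once.
- **Background genes**: the pipeline measures 850 additional
  unperturbed genes by default so the differential fraction is a few
  percent, the scale seen in genome-wide screens. This matters:
  quantile normalisation assumes most genes unchanged, and a generator
  that perturbs a fifth of the matrix visibly shrinks the planted
  effects.
- **Gene sets**: enriched sets draw 80% of members from the perturbed
  genes, background sets uniformly; serialisation order is fixed so a
  fixed seed reproduces GMT bytes.
- **Annotations**: the ortholog map is 1:1 except for configured counts
  of 1:many and many:1 cases; the disease list is drawn with a
  configured odds ratio against the perturbed genes (1.0 = independence,
  used for calibration tests); regulons are the out-edges of every node
  with out-degree ≥ 3; the bioactivity corpus plants one target whose
  actives are high-similarity (0.7–0.9) neighbours of the query
  fingerprint, with decoy targets held by low-similarity compounds of
  alternating activity.

**What the generator does not emulate**: count-level noise (data are
Gaussian on log2 directly, since the pipeline consumes log2 abundances),
read-level artefacts, mean–variance dependence, correlated gene
programs beyond the planted cone, real chemistry in synthetic
fingerprints, and real identifier vocabularies. Passing recovery tests
therefore demonstrates correctness of the inference machinery under the
stated generative model, not performance on any real dataset.

## Numerical and design choices

- Expression is generated and analysed on log2; no count model.
- All randomness flows through explicit integer seeds;
  `numpy.random.default_rng` children are derived per component.
- Exact permutation nulls are used whenever ≤ 8 nodes are measured;
  Monte-Carlo otherwise. p-values are plain exceedance fractions.
- Ties everywhere break deterministically (lexical ids, stable sorts).
- Degenerate inputs: single-sample matrices, empty contrast tables,
  empty backgrounds, empty ortholog maps, rank-deficient designs (the
  error names the aliased terms), zero-variance contrasts (SE 0 maps to
  p 0 for nonzero effects, p 1 otherwise), and empty fingerprints all
  raise or are defined explicitly rather than propagating NaNs.
- Problem sizes in the test and acceptance suites (150-node networks,
  ~1,000-gene matrices, 20-seed recovery loops, 100–200-seed
  calibration loops) are the package's chosen desk-scale defaults; they
  keep every planted signal comfortably detectable while each suite
  runs in minutes.

## Known limitations

- The fixed-effect plate adjustment under-states uncertainty when plate
  effects are large and designs unbalanced.
- Averaged p-values after ortholog expansion are not valid p-values;
  they are reproduced as a convention (see above).
- The kNN target predictor shares an interface, not calibration, with
  random-forest stacks; its probabilities are similarity votes.
- Causal reasoning assumes the signed network is correct and complete;
  consensus nodes inherit any network bias.
- The sign-flipped-network symmetry (identical ranking with inverted
  hypothesis signs) holds only at path length 1; the exact symmetry at
  all depths is in the observations: negating every observed state is
  equivalent to inverting every hypothesis sign.
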