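# Methods

This note documents the statistical machinery in `fibermeta`, the
assumptions behind it, the defaults and why they were chosen, and what the
synthetic-data generator does and does not emulate.

## Data model

Counts are OTU × sample matrices of non-negative integers; orientation is
explicit and never guessed. Sample metadata carries subject, study, a
binary before/after timepoint, and a collection-order integer that drives
pairing. Distance matrices are symmetric with a zero diagonal
(`skbio.DistanceMatrix`); trees are rooted `skbio.TreeNode` objects with
non-negative branch lengths on every edge (the root's is optional). All
text formats are UTF-8 TSV/FASTA/Newick with "." as the decimal point.

## Rarefaction and alpha diversity

Rarefaction draws, for each sample, a multivariate hypergeometric sample of
`depth` reads without replacement (`numpy`'s generator supplies the exact
distribution). Samples below the depth are dropped with a warning. The
default depth is the minimum retained-sample total — the largest depth that
keeps every sample.

Shannon entropy is reported in nats, and the Simpson index as the
complement 1 − Σ p². Metrics are computed per rarefaction iteration and
averaged over `n_iter` (default 1,000) iterations; averaging is the stabler
convention when the single-draw alternative is not dictated, and a single
draw is available by setting `n_iter=1`. The paired response test selects
per subject the earliest-order "before" and latest-order "after" sample and
applies a standard paired *t*-test to the iteration-averaged metrics.
Percent change defaults to the relative form 100·(after − before)/before;
an absolute difference-of-means variant is a keyword away, since both
conventions circulate for this quantity.

Degenerate paired tests are flagged rather than hidden: identical vectors
give t = 0, p = 1; constant non-zero differences give an infinite t with
the smallest representable p.

## Beta diversity

Bray-Curtis dissimilarity d(u,v) = 1 − 2Σmin(uᵢ,vᵢ)/(Σu + Σv) is computed
on √-transformed rarefied counts (the square root damps dominant taxa), and
the matrices are averaged element-wise over rarefaction iterations.

PERMANOVA follows the Gower-centering formulation: G = −½ J D² J, with
sequential (Type-I) sums of squares from nested hat-matrix projections —
subject entered first, then timepoint — so the timepoint term measures what
the intervention explains *after* inter-individual differences. Pseudo-F
per term uses the common residual; p-values come from free row/column
permutations of the distance matrix with the (1+b)/(1+m) convention and
ties counted as exceedances, and an exhaustive mode enumerates all n!
permutations for small n. Free permutation matches the default of the
standard implementation of this model; it is statistically liberal for the
timepoint term when subject effects are strong, which is why the synthetic
calibration checks use label-random nulls.

The dispersion check embeds the distance matrix by principal coordinates
retaining negative eigenvalues: a sample's squared distance to its group's
arithmetic centroid is the real-axis squared distance minus the
imaginary-axis one, floored at zero before the square root. A one-way F on
these distances is tested by permuting group labels against the observed
distances (the convention of the reference implementation). Centroids are
used rather than spatial medians for determinism and closed-form
testability; the reference tool defaults to medians, so dispersion p-values
can differ slightly from it.

## Differential abundance

The estimator is a deliberately simple member of the DESeq2 family,
chosen because the cross-study aggregation needs per-study log₂FC signs
and magnitudes rather than per-study inference, and because every step is
specifiable and testable:

- **Normalization** — median-of-ratios size factors against the
  geometric-mean reference over OTUs positive in all samples. When no such
  OTU exists, an optional fallback uses a +0.5 pseudo-count reference
  restricted to OTUs present in at least half the samples; the restriction
  matters, because a median taken over near-zero OTUs no longer tracks
  sequencing depth.
- **Effect size** — log₂ of the ratio of normalized group means, with a
  pseudo-count `pseudo/median(size factors)` applied only when a group
  mean is exactly zero (flagged per OTU), so well-observed OTUs are not
  biased.
- **Dispersion** — per-OTU method of moments on pooled within-group
  residuals, α = max((s² − Poisson)/μ², 1e-8). No shrinkage toward a
  fitted mean-dispersion trend.
- **Inference** — delta-method standard error of the log ratio from
  Var(μ_g) ≈ Σⱼ(μ_g/sⱼ + αμ_g²)/n_g², a two-sided normal Wald p, and
  Benjamini–Hochberg adjustment.

Known limitations, by design: on paired data with strong subject effects
the unpaired Wald test is conservative (the dispersion estimate absorbs
between-subject variance that the within-subject contrast cancels), so
per-study significance under-calls; and when responders are a large share
of the community the median-of-ratios reference itself shifts,
attenuating fold changes (measured ≈ −0.2 log₂ units at a 20% responder
fraction, ≈ −0.04 at 5%). Calibration claims therefore refer to
exchangeable samples and minority responder fractions — the regime the
model assumes.

Responder classification uses padj < 0.05 with |log₂FC| cutoffs 0 or 0.58
(a 1.5-fold change) for significance, while the positive/negative trait
sets split *all* tested OTUs by sign, zeros excluded — the same sets that
feed the phylogenetic analysis.

## Cross-study aggregation

Per study, OTUs are dropped when their summed count is below 10 or they
occur in fewer than 3 samples (either failure removes them), then a
prevalence filter keeps OTUs present in ≥ 50% of samples (boundary
inclusive). OTUs present — in the prevalence sense — in at least 3 studies
(inclusive; the stricter "more than 3" reading is a keyword) get the
unweighted mean of their per-study log₂ fold changes over exactly the
studies where they are present. The mean's sign is the response trait;
|mean| > 1 marks top responders. All widespread OTUs enter the average,
not only significant ones.

## Phylogenetic conservation

Pairwise p-distances exclude, per pair, sites where either sequence has a
gap or ambiguity. Neighbor joining is the Saitou–Nei Q-criterion
agglomeration with deterministic tie-breaks; a negative estimated pendant
length is clamped to zero with the deficit moved to its sibling so the
joined pair still spans its distance. On additive matrices the algorithm
is exact (topology and branch lengths), which the tests verify against the
generating trees and an independent implementation. Outgroup rooting
bisects the outgroup's pendant edge at its midpoint.

consenTRAIT: every internal node whose descendant tips are ≥ 90%
trait-positive, with at least two positive tips, qualifies; only maximal
qualifying nodes are kept. A clade's depth is the mean path length from
its root to **all** its descendant tips (averaging over positive tips only
is a keyword switch); positive tips outside any qualifying clade are
singletons at half their terminal branch — the convention of the original
algorithm, and configurable off. τ_D is the unweighted mean over clades
and singletons. Significance reshuffles trait labels across tips
(positive count preserved), p = (1 + #{τ ≥ τ_obs})/(1 + n_perm). The
two-positive-tip requirement keeps "clade" and "singleton" disjoint
categories, and the cutoff must exceed 0.5 for maximality to be
well-defined.

Because a single 1/0 coding cannot yield separate positive and negative
depths, the conservation report runs consenTRAIT twice — once with
positive responders coded 1, once with negative responders coded 1 — on
the tree sheared to the trait OTUs (plus outgroup). The Mantel comparison
of two trees' distance matrices uses Spearman rank correlation of the
lower triangle with a one-sided permutation test.

## Synthetic data

The generator emulates the structure of multi-subject fiber-intervention
data, with all randomness from one seeded generator and per-study
substreams derived from (seed, study index) so adding studies never
perturbs earlier ones:

- a pure-birth tree rescaled to a mean root-to-tip depth of 0.15
  (16S-scale distances), with responder clades selected nearest a target
  depth of 0.02 — the depth scale on which such traits are conserved;
- lognormal rank-abundance baselines (σ = 1.5 in log units, typical of gut
  communities), per-study occupancy masks (each OTU present with
  probability 0.8);
- per-subject, per-OTU log-abundance offsets ~ N(0, σ_subject²) and
  per-sample noise ~ N(0, σ_noise²); "after" samples add
  effect·ln2·trait to responders;
- expected counts scale the exponentiated log-abundances by a per-study
  constant normalizer, so a planted effect of 1 log₂ unit is an exact
  twofold expected change — library-size variation is injected separately
  as lognormal depths (CV 0.3, mean 5,000), making rarefaction matter;
- counts are gamma-Poisson with dispersion 0.3 (Poisson in the limit 0);
  negative binomial rather than Dirichlet-multinomial because it matches
  the downstream abundance model.

The default preset conditions — σ_subject = 1.1, σ_noise = 0.30,
effect = 1.0 on 3 positive and 3 negative clades, 20 subjects with one
before and one after sample each — were calibrated once so the Bray-Curtis
partition lands at the structure characteristic of real interventions:
subject R² ≈ 0.82, timepoint R² ≈ 0.015 (declared as the preset's planted
targets). The end-to-end conservation bundle plants 8+8 clades (~30% of
tips) instead, emulating data whose responses are strongly
clade-structured across the tree; with only 3+3 planted clades the
aggregated signs of non-responders are coin flips and the permutation test
has little power against that singleton noise.

What the generator does **not** emulate: taxonomic composition,
phylum-level structure, cross-study primer/region differences, chimeras or
sequencing error (OTU filtering is exercised on rare planted OTUs, not on
realistic artifacts), correlated OTU dynamics beyond the subject effect,
and responder fractions tied to real fiber types. Passing tests
demonstrate the machinery is correct and calibrated under this model, not
that real data meet its assumptions.

## Numerical choices and problem sizes

Permutation p-values are (1+b)/(1+m) everywhere, ties inclusive, so p is
never zero. PERMANOVA hat matrices use pseudo-inverses (rank-deficient
designs degrade gracefully); R² partitions are exact to 1e-10. The NJ
tie-break picks the lexicographically smallest pair. Tree rescaling in the
generator enforces the target mean depth to 1e-9.

The test and acceptance runs use deliberately modest sizes — 200-OTU
trees, 8 studies × 20 subjects, 100–1,000 rarefaction iterations, 199–999
permutations — chosen so the full suite completes in a few minutes on one
CPU while every statistical claim retains its stated tolerance; the
pipeline defaults mirror the conventional analysis parameters (1,000
iterations, 999 permutations, cutoff 0.9, padj < 0.05).
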