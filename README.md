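# fibermeta

Cross-study meta-analysis of short-term dietary-fiber interventions on the
human gut microbiome, as a tested, reusable Python library.

Fiber-intervention 16S rRNA studies share a difficult structure: who a
stool sample comes from explains the overwhelming majority of compositional
variance, while the intervention itself moves a small, consistent set of
taxa. `fibermeta` implements the full analysis chain for asking whether
those taxon responses are consistent across studies and phylogenetically
conserved:

1. **Alpha diversity** — iterated rarefaction (sampling without replacement,
   many iterations, metrics averaged), Shannon *H* = −Σ *p*ᵢ ln *p*ᵢ,
   Simpson complement 1 − Σ *p*ᵢ², observed richness, and a paired *t*-test
   on one (earliest-before, latest-after) sample pair per subject.
2. **Beta diversity** — Bray-Curtis dissimilarity averaged over rarefaction
   iterations of √-transformed counts, partitioned by a sequential (Type-I)
   PERMANOVA, `distance ~ subject_id + timepoint`, with permutation
   p-values and a PERMDISP-style dispersion-homogeneity check.
3. **Differential abundance** — per-study negative-binomial Wald tests on
   non-rarefied counts with median-of-ratios size factors, moment-estimated
   dispersion, and Benjamini–Hochberg adjustment (a deliberately simple,
   fully specified estimator in the DESeq2 family).
4. **Cross-study aggregation** — abundance/occupancy and 50% prevalence
   filters, then unweighted averaging of log₂ fold changes for OTUs present
   in ≥ 3 studies; the sign of the mean assigns a binary response trait and
   |mean log₂FC| > 1 marks top responders.
5. **Phylogenetic conservation** — p-distances from aligned 16S sequences,
   neighbor joining with outgroup rooting, and consenTRAIT: the mean depth
   τ_D of the maximal clades in which ≥ 90% of tips share the response
   trait, with a trait-shuffling permutation test, run separately for
   positive and negative responders.

A first-class synthetic-data generator (`fibermeta.synthetic`) emulates the
multi-study structure — subject-dominated variance, study-specific OTU
occupancy, overdispersed counts at variable library sizes, and responder
OTUs planted in clades of known depth — so every stage is testable against
planted ground truth without downloading anything.

## Worked example

Partition one simulated study's Bray-Curtis variance
(`examples/03_beta_permanova.py`):

```text
subject_id   df= 19 R2= 83.1% F=  5.34 p=0.001
timepoint    df=  1 R2=  1.3% F=  1.61 p=0.006
residual     df= 19 R2= 15.6%
dispersion: F=1.11 p=0.297
```

Subject identity explains 83% of compositional variance and is highly
significant; the fiber timepoint explains a small but real 1.3% (p = 0.006
over 999 permutations) — a genuine mean shift, since the dispersion test is
non-significant. Aggregating eight such studies and running the paired
conservation analysis (`examples/06_conservation_depth.py`) prints:

```text
positive responders: n=58, tau_D=0.0106, p=0.001, 8 clades + 22 singletons
negative responders: n=142, tau_D=0.0139, p=0.001, 24 clades + 35 singletons
```

τ_D is the mean depth (in 16S distance units) of the clades in which at
least 90% of tips respond in the same direction; both responses are
conserved far deeper than the trait-shuffled null (p = 0.001).

Each script in `examples/` is a short narrative of one capability:
simulation, alpha response, variance partitioning, differential abundance,
cross-study traits, conservation depth, and the full pipeline. A thin CLI
mirrors the stages (`fibermeta simulate|alpha|beta|da|aggregate|conservation|run`),
driven by a YAML config for `run`.

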