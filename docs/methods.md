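# Methods

This note records the models, parameter choices and numerical decisions
behind screenforge, and what its synthetic validation does and does not
establish.

## Screen model and simulator

The simulator generates the complete causal chain of a pooled knockout
resistance screen, keeping exact per-guide cell counts at every stage so
that inference can be compared against realized (not just nominal) truth.

**Library.** `n_genes` genes × `guides_per_gene` (default 3), optional
miRNA targets (4 guides each) and `n_controls` non-targeting guides with
random distinct 20-nt spacers. Initial representation is log-normal with
σ = 0.5 (`library_sigma`): pooled plasmid libraries are never uniform,
and a log-normal with this spread reproduces the right-skewed count
distributions and several-fold inter-quartile ranges seen in real
plasmid-pool sequencing.

**Infection.** Each exposed cell receives Poisson(`moi`) integrations
(default MOI 0.3, the standard low-MOI design: the infected fraction is
1 − e^−0.3 ≈ 0.259 and ≈ 86% of infected cells carry a single guide).
Every integration draws a guide from the library distribution and founds
an independent lineage; multi-integration cells therefore contribute one
lineage per guide, a deliberate simplification that is accurate when
multiples are rare. `coverage` (default 400) is the number of *infected*
cells per guide — the convention used when screens quote coverage as
harvested mutant cells over library size — so the number of exposed
cells is `coverage · n_guides / (1 − e^−moi)`.

**Selection.** Each of `selection_rounds` (default 3) drug rounds
multiplies a guide's expected abundance by its gene's fitness
multiplier, then resamples multinomially back to the constant pool size.
A resistance gene with multiplier m enriches ≈ m^rounds in relative
abundance (64× at the default m = 4, 3 rounds). Fitness acts on the
gene, not the guide: all guides of a gene share its multiplier. The
vehicle arm runs the same rounds with all-neutral fitness, so both arms
carry identical drift variance.

**Bottlenecks.** Implantation and metastatic seeding are draws *without
replacement* (multivariate hypergeometric) of `bottleneck_primary`
(default 10% of the pool) and `bottleneck_metastasis` (default 2%)
cells, followed by one further round of in-vivo drug selection. These
defaults give the qualitative signature of real in-vivo screens: primary
tumors retain most of the library, metastases collapse to tens of
lineages, and metastasis replicates diverge from everything else.

**Sequencing.** Reads per guide are gamma-Poisson (negative binomial)
with mean proportional to guide frequency × `seq_depth` (default 500
reads/guide) and dispersion `nb_dispersion` (default 0.01, a typical
replicate-level technical overdispersion for amplicon counting;
dispersion 0 gives the exact Poisson limit). Optional FASTQ emission
writes one read per counted molecule with per-base substitution errors
at `error_rate`.

With these defaults the simulator reproduces the headline behaviour of
a well-executed screen — replicate log-count correlation r > 0.9 for
un-bottlenecked samples, full library detection in cell samples — which
is the regime the downstream statistics are validated in.

**What the simulator does not model:** guide-efficiency heterogeneity,
off-target effects, copy-number artifacts, PCR jackpotting beyond NB
overdispersion, cell-cycle/density dependence, and any
pharmacokinetics (drug concentrations are labels, not model inputs).
Passing recovery tests on this generator shows the *pipeline* is
correct and calibrated under the stated noise model; it does not show
that real screens meet that model.

## Quantification

Guide counting is exact-match hash lookup of the spacer window
(configurable offset, or anchored on constant flanks), with an optional
single-substitution neighbourhood search (60 lookups per read) when the
exact lookup misses. This replaces an external aligner: for fixed-length
barcode quantification, local alignment reduces to windowed exact/1-mm
matching, and the hash approach is deterministic and dependency-free.
Reads matching more than one guide — including reads hitting spacers
shared by several guides — are counted *ambiguous* and excluded, the
multi-mapping discard semantics of alignment pipelines.
Reverse-complement matching is off by default (library-prep orientation
is construct-specific) and flag-switchable. No quality filtering or
adapter trimming is attempted.

## Differential abundance

**Normalization.** Median-of-ratios size factors: factor_s =
median over guides of counts[g,s] / geometric-mean_g(counts), guides
containing any zero excluded, then rescaled to geometric mean 1 (so
normalized counts have a well-defined absolute scale). If no guide is
everywhere-nonzero (possible after severe bottlenecks) the strict
estimator raises; pipeline-facing callers use `method="auto"`, which
falls back to total-count factors with a warning.

**Dispersion.** Per-guide method-of-moments α̂ = (s² − μ)/μ² on
normalized counts, using the *within-group pooled* variance so real
condition effects do not inflate dispersion. The mean–dispersion trend
α(μ) = a₁/μ + a₀ is fit by weighted least squares to *bin-averaged,
unclipped* moment estimates (≈20 log-mean bins): per-guide estimates at
2 residual df are enormously noisy and clipping them at zero before
fitting biases any direct regression downward, whereas bin means of the
unclipped estimates are nearly unbiased. The final dispersion blends
raw and trend with weight dof/(dof + 16) on the raw estimate — an
empirical-Bayes-style squeeze: at the common 2-vs-2 design (dof = 2)
the per-guide estimate carries little information and gets weight 1/9;
with many replicates it dominates. The fixed prior df of 16 was chosen
so that the Wald test is calibrated (see below) at few-replicate
designs without discarding per-guide information in large ones. An
explicit `shrink_weight` overrides the adaptive rule. With zero
residual df the model is trend-only (warning).

**Testing.** For each guide and group the NB log-link GLM reduces to a
one-dimensional score equation Σ_s (k_s − s_s m)/(1 + α s_s m) = 0,
solved by damped Newton iteration in log m, vectorized across all
guides simultaneously (exact for a two-group design; ~10⁵ guides fit in
well under a second). Wald statistic: contrast of fitted log-means over
the Fisher-information SE; two-sided normal p-values floored at 1e-300.
Groups with all-zero counts are clipped at half a normalized count so
the contrast stays finite; guides zero everywhere report log2FC 0,
p 1, flagged. The *reported* log2FC is
log₂((mean_T + 0.5)/(mean_C + 0.5)) on normalized group means — the
pseudo-count keeps it finite and slightly shrinks extreme ratios; it is
a display/thresholding value, while testing uses the GLM fit.

**Calibration.** Under null NB simulations at the screen's own 2-vs-2
design (2000 guides, dispersion 0.1), per-guide p-values are uniform
(0/20 seeded KS tests rejected at α = 0.01) and type-I error at nominal
0.05 is ≈ 0.056; with the raw/trend weight fixed at 0.5 the same
simulations reject uniformity in 20/20 seeds (type-I ≈ 0.09), which is
why the adaptive weight is the default. A known residual: with 2
replicates per group the normal reference is slightly light-tailed
(KS D ≈ 0.02 even at known dispersion).

**Not implemented** (by design): multi-factor designs, Cook's-distance
outlier refitting, independent filtering, and fold-change shrinkage —
reported fold changes are unshrunk.

## Gene aggregation

Guides collapse to targets (non-targeting controls excluded; miRNA
targets aggregated identically, class retained). Mean log2FC is the
arithmetic mean of member guides' log2FC (a flag switches to the log of
the mean linear FC — "mean fold change" is ambiguous and both readings
are provided). P-values combine by Fisher's method, X² = −2Σln pᵢ with
upper-tail χ² at 2k df, inputs clipped to [1e-300, 1]. By default the
two-sided guide p-values are combined; `one_sided=True` converts them
to enrichment-only p-values (p/2 on the enriched side, 1 − p/2
otherwise) first, which is the recommended mode for positive-selection
screens — a gene with consistently *depleted* guides should not score.
BH q-values are computed across all aggregated targets; genes whose
guides are zero in every sample are dropped from the family (logged).
Note Fisher's method assumes independent guide p-values; guides of one
gene share biology, so combined p-values are calibrated under the
simulator (independent guides) but anti-conservative to the extent real
guide effects correlate.

## Hit calling

All threshold comparisons are strict (count > 100 AND log₂FC > 3). The
"count" used for thresholds and for the trend ordering is the
size-factor-normalized, replicate-averaged count of the treated
condition (a raw-count switch exists): cross-condition ordering on raw
counts would largely reflect sequencing depth. Top-N ranking (defaults
600/400/200 for the drug/tumor/metastasis comparisons) is by log2FC
among guides passing the count filter, ties broken by smaller p then
guide id; rank-by-count is available, and no claim is made about which
ranking the original screen design used. The core set is the literal
intersection of the per-comparison top-N guide lists; core genes are
their distinct targets. The trend group requires strictly increasing
normalized mean counts metastasis > primary tumor > treated cells.

## QC

Pearson correlations are computed on log₂(normalized + 1) (flag for
linear); zero-variance samples yield NaN with a warning rather than an
arbitrary value. Two-sample KS tests use the asymptotic p-value
(adequate at library scale; exact small-sample p is not implemented)
over all sample pairs. ECDFs are reported per sample over guide counts.

## Determinism and problem sizes

Every stochastic component draws from `numpy.random.default_rng` seeded
from a single configuration seed; identical configurations reproduce
outputs byte-for-byte. Validation problem sizes — 2000-guide null/FDR
tables over 20 seeds, 100-gene/600-guide recovery screens at 400×
coverage and 500× depth, ≤100-element oracle instances — were chosen as
the smallest sizes at which the asymptotic checks (KS against uniform,
3-SE moment bounds, FDR averages) are sharp; the whole suite and the
acceptance script each run in seconds on one core.

## Known limitations

- The Wald test's normal reference is mildly optimistic at 2 replicates
  (see Calibration); an exact/conditional test is out of scope.
- Fisher combination ignores intra-gene guide correlation.
- The quantifier handles substitutions only — indel-containing reads go
  unassigned, slightly deflating counts at high error rates.
- The simulator's bottleneck + one-round-regrowth model of in-vivo
  stages is a coarse abstraction of engraftment and metastatic
  dynamics; it generates realistic marginal heterogeneity but not
  spatial or temporal structure.
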