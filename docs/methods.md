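# Methods

This note documents the statistical procedures implemented in `triomics`,
the assumptions behind them, the defaults and why they were chosen, and
what the synthetic-data generator does and does not emulate.

## The screening problem

Paired designs with very few biological replicates (here: three matched
fresh/frozen sample pairs) cannot support elaborate joint models. The
screen therefore combines three *independent lines of evidence*, each
simple enough to be trustworthy at n = 3 per group, and keeps only features
supported by all three: threshold-based differential calling feeding
pathway co-enrichment, a gene–protein correlation network, and O2PLS joint
loadings. Requiring consensus trades sensitivity for specificity — the
intended outcome is a list of one or a few candidates worth wet-lab
follow-up, not a complete catalogue.

## Differential statistics

Per feature, a two-sample pooled-variance (Student's) t-test on
log2-transformed abundance (`log2(x + eps)`, default `eps = 1e-3`), df =
n₁ + n₂ − 2, two-sided p, adjusted across features by Benjamini–Hochberg
step-up (delegated to statsmodels). Welch's form is available behind a
flag. Zero-pooled-variance features are flagged degenerate with p = 1
(equal means) or p = 0 (unequal), never dropped silently.

Fold change is `log2((mean_PS + eps)/(mean_FS + eps))` on the raw
abundance scale, oriented frozen-over-fresh so that "down" means loss after
cryopreservation. The pseudocount matters only for features collapsing to
(near) zero in one group; with a unit pseudocount a feature at ~2500 that
vanishes lands near −11.28 log2 units, the magnitude scale typical of
transcript tables from such designs. `eps` is configurable; the transform
used is recorded in the output header since whether such pipelines test
FPKM, log-FPKM or counts is rarely stated.

Calls use strict inequalities — |log2FC| strictly above the threshold AND
FDR strictly below alpha — with the field-standard gates: 1.0 for
transcripts, 0.263 (log2 of 1.2, the usual TMT ratio-compression-aware
cutoff) for proteins, alpha 0.05.

`ttest_from_summary` reconstructs the same pooled test from printed
group summaries (mean ± SEM, n), with sd = SEM·√n; it reproduces the
letter-code significance patterns of sperm-quality tables exactly.

## Over-representation and co-enrichment

ORA is the exact hypergeometric upper tail P(X ≥ k); each set is
intersected with the universe before testing. The universe is the
*quantified* feature space of the relevant omics (not a whole-genome
annotation): with desk-scale designs the quantified space is the only
defensible background. Co-enrichment pools differential genes with
id-mapped differential proteins (selection) against the union of both
quantified spaces in gene space (universe); per-set output records which
members came from which omics. Significance for co-enriched pathway lists
uses raw p < 0.05 — the convention for combined-omics pathway reporting —
with a BH column emitted alongside. Proteins without an id-map entry are
excluded and logged, never silently discarded.

## GSEA

Weighted Kolmogorov–Smirnov running sum over the full ranking: walking down
the list, the sum rises by |score|^weight (normalized over set members) at
members and falls by 1/(N−K) otherwise; ES is the extremum, the leading
edge the members up to it. Ranking ties break lexicographically by feature
id, so results are deterministic. Defaults: weight 1 (classic), ranking
metric signed log2FC (caller-supplied; the metric is a free choice).

The null permutes *set membership labels*, not phenotype labels: with
three samples per group only 20 distinct relabelings exist, far too few
for a permutation null. p is add-one smoothed, (1 + #extreme)/(n_perm + 1),
so it is never zero; NES divides ES by the mean of same-sign null ES.
A caveat worth knowing: with weight 1, null sets that draw even one
large-|score| feature produce large weighted ES values, so a set must be
*coherently* top-ranked — not merely contain a few differential members —
to reach small permutation p. This is a property of set-permutation GSEA
generally, not of this implementation.

## Pearson network

All gene × protein pairs between two sample-aligned matrices are tested
(log2 scale by default, matching the differential stage); an edge requires
|ρ| > 0.8 AND two-sided p < 0.05, both strict, with no multiple-testing
correction (the conventional gate for such networks; a BH mode exists but
is off by default). At n = 6 the p < 0.05 gate corresponds to |ρ| > 0.811
and is therefore the binding constraint. Correlations pool fresh and
frozen samples — group structure is deliberately not partialed out, since
the screen wants features whose joint gene/protein swing tracks the
treatment. Zero-variance features have undefined correlation and are
dropped with a logged reason (not treated as ρ = 0). Degree ranking sorts
genes by edge count, ties lexicographic.

## O2PLS

Estimation follows the standard route: center columns (unit-variance
scaling optional, off by default — with multiplicative omics data the log2
transform already homogenizes scales, and variance scaling at n = 6 is
noisy), take the joint loadings W, C as the leading singular vectors of
XᵀY, optionally extract block-orthogonal components from what the joint
projection leaves behind (the EᵀT construction), deflate, and re-fit the
joint part. Defaults are one joint and zero orthogonal components: with six
samples more components are barely identifiable. Component counts and
preprocessing are recorded in the model metadata.

Signs are fixed deterministically (largest-|element| of each loading column
made positive) so repeated runs and oracle comparisons agree. Two
orthogonality facts hold exactly and are verified in tests: orthogonal
scores are orthogonal to their own block's re-fit joint scores, and at
extraction time each orthogonal direction has zero covariance with the
opposite block's joint scores (recorded as a model diagnostic). After the
final re-fit the latter holds only approximately — the re-fit rotates the
joint basis — which is an inherent property of the deflate-then-refit
estimator, not a numerical defect.

The top-k shortlist (default k = 25 per block, i.e. 25 genes AND 25
proteins) ranks features by max |joint loading| across joint components,
ties lexicographic. Loadings that are numerically zero relative to the
block's largest are excluded — on degenerate inputs (e.g. noise-free data)
they would otherwise fill trailing slots purely by id order. The consensus
screen's O2PLS set requires, by default, presence in *both* blocks' top-k
lists (mode `both_blocks`); a union mode exists. The both-blocks reading is
what makes the O2PLS screen genuinely cross-omics: a feature must
contribute to the shared covariation as transcript and as protein.

## Consensus

Set algebra runs in gene-symbol space after case-insensitive normalization;
protein ids translate through the id map, and unmappable ids are logged.
The Pearson screen includes both endpoints of every significant edge
(candidate lists of this kind mix genes and proteins); a hub-neighborhood
mode restricted to the top-5 degree genes exists, with the choice recorded
in the report metadata. Empty intersections are a valid outcome. Candidate
ranking sorts by supporting-screen count, then network degree, then max
|joint loading|, then id.

## The synthetic generator

Abundances are log-normal: Gaussian on the log2 scale around per-feature
baselines (uniform 4–10 log2 for transcripts, 10–16 for reporter
intensities), with planted group effects added to the frozen group and
per-feature noise of sd `noise_sd_log2`. Defaults are a desk-scale version
of the real design: 3 vs 3 samples, 500 genes, 300 proteins (all proteins
id-mapped), 25 differential genes at ±2.0 log2 (5% of features,
matching the differential fraction such studies report) and 15 differential
proteins at ±0.6, signs 85% down (cryostress skews losses), a 20-member
planted pathway with contributors from both omics plus unaffected members,
10 cross-omics correlated pairs, 5 decoy gene sets, and a motility/viability
phenotype that is a linear function of the candidate's log2 abundance
(slope 24 %/log2-unit, noise sd 1.5%) — chosen so fresh/frozen phenotype
means land in the realistic 83/35% range.

**Noise level.** `noise_sd_log2 = 0.05` (≈3.5% CV) was fixed by a
design-time power analysis: at 3 vs 3 with the printed gates, a 0.6-log2
protein effect must survive BH across ~300 proteins, which requires
per-feature log2 sd ≈ 0.05 (pass probability 0.998; at sd 0.10 it drops to
0.52). That is at the clean end of, but within, the technical precision
reported for TMT reporter summed intensities and deep RNA-seq. The
generator thus represents a *well-powered instance* of the design — the
regime in which the published screen itself must have operated to find
anything at the same thresholds.

**Latent factor.** Cross-omics correlation in the planted pairs comes from
a shared per-sample latent factor, centered within each group so that group
means (hence fold changes) are untouched. The loading is
a = σ·√(ρ/((1−ρ)·c)) with c = (n−1)/n the centering shrinkage, which hits
the target pair correlation in expectation; with zero noise the loading is
zero and the generator is exactly deterministic (realized group-mean log2
differences equal planted effects to machine precision). The consensus
candidate's pair is the one exception: its cross-omics correlation is
inherited from its shared differential response (≈0.98 under defaults,
above the 0.95 target), because adding latent variation on top would
inflate its within-group variance and mask the planted effect at n = 3 —
the candidate must, by construction, survive the threshold screens.

**Truth layout.** The planted differential gene set deliberately saturates
the top-k joint-loading shortlist (n_de_genes = top_k = 25): if shortlist
slots were left to noise-level loadings, features planted as
single-omics contributors could leak into the O2PLS screen by chance and
the planted candidate would not reliably be the *unique* triple hit, which
is the generator's contract. Decoy sets are drawn from unstructured
features only, keeping the ground truth unambiguous. Non-candidate latent
pairs live outside the planted pathway, so they exercise the network and
O2PLS machinery without entering the enrichment screen.

**What the generator does not emulate:** sequencing reads or spectra,
missing values, TMT ratio compression, batch structure, or correlated
noise between features. Passing tests on this generator demonstrate that
the screen's logic recovers a planted signal under clean, well-powered
conditions; they do not demonstrate robustness to the messier failure
modes of real data.

## Numerical choices and degenerate inputs

- Half-up decimal rounding (not banker's) for the mapping-rate percentage,
  matching how such figures are printed.
- Exact collinearity (|ρ| ≥ 1 − 1e-14) reports p = 0 directly rather than
  relying on tail numerics.
- BH inputs outside [0, 1] and negative counts are domain errors; empty
  candidate sets and empty intersections are results, not errors.
- Pipeline stage failures are re-raised with the stage name attached.
- All simulation randomness flows from one `numpy` generator seeded by
  `SimConfig.seed`; identical configs give byte-identical outputs.

## Problem sizes

The test suite and the acceptance script run the full screen on the
500-gene/300-protein default at 50 replicate seeds, the oracle-equivalence
suites on exhaustive small instances (hypergeometric N ≤ 12, GSEA rankings
≤ 10 features, 100 random 6-sample O2PLS instances), and Monte-Carlo checks
on down-scaled configurations (80 genes, up to 50 samples per group). These
sizes were chosen to make every distributional claim checkable in seconds
while keeping the per-replicate statistics identical to the default design.

## Known limitations

- With three samples per group, the network's edge p-values are coarse
  (only the |ρ| gate binds beyond p < 0.05 at n = 6) and the O2PLS joint
  subspace is limited to one reliable component.
- The spec of the O2PLS orthogonal parts is estimator-dependent: the
  deflate-then-refit route does not keep orthogonal scores exactly
  uncorrelated with the *re-fit* opposite joint scores (see above).
- Reproducing a specific published pathway list requires the same
  annotation database and version; enrichment here is tested against its
  own exact-combinatorics oracle, not against any external database.
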