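# triomics

**Paired transcriptome–proteome consensus candidate screening.**

`triomics` implements the three-method integration screen used to
prioritize molecular candidates from matched fresh/frozen (FS/PS) sample
designs — the setting of sperm cryopreservation studies, where a handful of
paired samples are profiled by RNA-seq and TMT proteomics and the goal is
to find the few features whose loss tracks the loss of cell function. A
feature is a *consensus candidate* when it survives all three screens:

1. **Differential + co-enrichment.** Per-feature pooled-variance t-tests on
   log2 abundance with Benjamini–Hochberg FDR; genes gated at
   |log2FC| > 1, proteins at |log2FC| > 0.263, both at FDR < 0.05
   (strict inequalities). Differential genes and (id-mapped) differential
   proteins are pooled into one gene-space selection and tested for pathway
   over-representation with the exact hypergeometric upper tail
   p = Σᵢ₌ₖ C(K,i)·C(N−K,n−i)/C(N,n).
2. **Bipartite Pearson network.** Every pathway-enriched differential gene
   is correlated with every pathway-enriched differential protein across
   the matched samples; edges require |ρ| > 0.8 and p < 0.05 (two-sided,
   from t = ρ·√((n−2)/(1−ρ²)) on n−2 df). Degree ranking identifies hub
   genes.
3. **O2PLS joint loadings.** Two-way orthogonal PLS on the full quantified
   blocks: X = TWᵀ + T_orth P_orthᵀ + E, Y = UCᵀ + U_orth Q_orthᵀ + F, with
   the joint subspace from the SVD of the cross-covariance XᵀY. Features in
   the top 25 |joint loading| of *both* blocks form the third screen.

The triple intersection (in gene-symbol space, case-insensitive) is the
consensus set. A GSEA implementation (weighted Kolmogorov–Smirnov running
sum with a set-label permutation null) and Table-style summary-statistics
t-tests (from mean ± SEM per group) round out the toolkit.

Because real paired-omics data of this kind need controlled access, the
package ships a **synthetic paired-omics generator** with planted ground
truth: log-normal abundances, planted group effects (2.0/0.6 log2 by
default), a shared per-sample latent factor driving cross-omics correlated
pairs (target ρ = 0.95), one planted pathway, and a phenotype linearly tied
to one planted consensus candidate. Every stage of the screen is testable
against this truth without downloads.

## Worked example

```python
import triomics as tm

res = tm.generate_paired_omics(tm.SimConfig(seed=7))
out = tm.run_pipeline(res.genes, res.proteins, res.id_map, res.gene_sets)
print(out.report.triple, res.truth.consensus_candidate)
```

Running `python examples/05_consensus_pipeline.py` prints:

```
screen sizes: KEGG-style co-enrichment = 15, Pearson network = 15, O2PLS top-loadings (both blocks) = 1
pairwise:     K^P = 15, K^O = 1, P^O = 1
triple intersection: ['G0000']
planted truth:       ['G0000']
```

Fifteen features carry co-enrichment and network support, but only the
planted candidate `G0000` also sits in the top-25 joint loadings of both
O2PLS blocks — the screen reduces 800 quantified features to one, and it is
the right one. Its provenance entry records the supporting statistics
(network degree 8, max |joint loading| 0.214). The other examples walk the
individual stages: the generator and its truth validation (`01`),
differential calling and the summary t-test that reproduces a
motility difference of 82.63 ± 3.55 vs 34.10 ± 2.90 (n=3/3) at
p = 4.5 × 10⁻⁴ (`02`), co-enrichment and GSEA (`03`), the network and
O2PLS diagnostics (`04`).

A thin CLI mirrors the library for shell use:

```bash
triomics simulate --seed 7 --outdir sim/
triomics run-all --config run.yaml --outdir out/
triomics qc mapping-rate --total 310699628 --unique 186669343   # -> 60.08
```

## Layout

```
src/triomics/    simulate, io, differential, enrichment, network, o2pls,
                 consensus, cli
examples/        one narrative script per capability
tests/           pytest suite (unit, property-based, end-to-end)
docs/methods.md  model assumptions, parameter rationale, limitations
```
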