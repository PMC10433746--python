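"""Synthetic paired transcriptome-proteome generator with planted truth.

The generator emulates a 3-vs-3 paired fresh (FS) / programmed-freezing
(PS) design: log-normal abundances (Gaussian on the log2 scale), planted
group effects on a subset of genes and proteins, a shared per-sample latent
factor that induces cross-omics correlation in a set of planted gene-protein
pairs, one planted pathway that is enriched in both omics, and a phenotype
(motility/viability style) linearly tied to one planted consensus candidate.

Layout of the planted structure (all bookkeeping is returned in
:class:`SyntheticTruth` so every downstream stage has a recoverable ground
truth):

* one *consensus candidate*: a shared-id feature that is differential in
  both omics, belongs to the planted pathway, carries the latent factor,
  and drives the phenotype -- the feature the full screen should single out;
* pathway members that are differential in exactly one omics (so the
  pathway is co-enriched with contributions from both layers) plus a few
  unaffected members;
* additional differential genes/proteins outside the pathway;
* latent-factor pairs outside the pathway (cross-omics correlated but not
  pathway-annotated), plus decoy gene sets drawn from unstructured
  features so the planted truth stays unambiguous.

The group effect is applied to the PS group, matching the convention that
"down" means reduced after freezing. The latent-factor loading is scaled to
the noise level so the target pair correlation holds in expectation; a
zero-noise configuration therefore has no latent variation at all and
realized group-mean log2 differences equal the planted effects exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError
from .io import (ExpressionMatrix, GeneSetCollection, IdMap, PhenotypeTable,
                 write_expression_matrix, write_gmt, write_id_map,
                 write_phenotype)

PATHWAY_NAME = "planted_pathway"
_DOWN_FRACTION = 0.85  # cryostress skews differential features downward


@dataclass(frozen=True)
class SimConfig:
    """Study-condition knobs for the paired-omics generator.

    Defaults mirror a desk-scale version of the 3-vs-3 cryopreservation
    design: 500 genes, 300 proteins (all protein ids mapped to genes),
    planted log2 effects of 2.0 on 25 genes (the |log2FC| > 1 gate) and 0.6
    (proteins; the |log2FC| > 0.263 gate), a 20-member planted pathway,
    10 latent-factor pairs at a target cross-omics correlation of 0.95,
    and log2-scale Gaussian noise with sd 0.05 (technical-replicate-grade
    precision; see the methods note for the power rationale).
    """

    n_genes: int = 500
    n_proteins: int = 300
    n_shared_ids: int = 300
    n_per_group: int = 3
    gene_effect_log2: float = 2.0
    protein_effect_log2: float = 0.6
    n_de_genes: int = 25
    n_de_proteins: int = 15
    latent_rho: float = 0.95
    n_planted_pairs: int = 10
    pathway_size: int = 20
    noise_sd_log2: float = 0.05
    n_decoy_sets: int = 5
    phenotype_beta: float = 24.0
    phenotype_noise_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_genes": self.n_genes, "n_proteins": self.n_proteins,
            "n_shared_ids": self.n_shared_ids, "n_per_group": self.n_per_group,
            "n_de_genes": self.n_de_genes, "n_de_proteins": self.n_de_proteins,
            "n_planted_pairs": self.n_planted_pairs,
            "pathway_size": self.pathway_size,
        }
        for name, v in counts.items():
            if v < 1:
                raise ConfigError(f"invariant violated: {name} must be >= 1")
        if self.n_shared_ids > min(self.n_genes, self.n_proteins):
            raise ConfigError("invariant violated: n_shared_ids <= "
                              "min(n_genes, n_proteins)")
        if self.n_de_genes > self.n_genes:
            raise ConfigError("invariant violated: n_de_genes <= n_genes")
        if self.n_de_proteins > self.n_proteins:
            raise ConfigError("invariant violated: n_de_proteins <= n_proteins")
        if not 0.0 <= self.latent_rho <= 1.0:
            raise ConfigError("invariant violated: latent_rho in [0, 1]")
        if self.noise_sd_log2 < 0:
            raise ConfigError("invariant violated: noise_sd_log2 >= 0")
        if self.n_planted_pairs > self.n_shared_ids:
            raise ConfigError("invariant violated: n_planted_pairs <= "
                              "n_shared_ids")


@dataclass
class SyntheticTruth:
    """Planted ground truth: what a perfect analysis should recover."""

    de_genes: dict[str, float]          # gene id -> signed log2 effect
    de_proteins: dict[str, float]
    planted_pairs: list[tuple[str, str, float]]
    pathway_name: str
    pathway_members: list[str]
    consensus_candidate: str
    phenotype_beta: float
    latent_loading: float
    config: SimConfig | None = None


class SimResult(NamedTuple):
    genes: ExpressionMatrix
    proteins: ExpressionMatrix
    id_map: IdMap
    gene_sets: GeneSetCollection
    phenotype: PhenotypeTable
    truth: SyntheticTruth


def _gene_id(i: int) -> str:
    return f"G{i:04d}"


def _protein_id(i: int) -> str:
    return f"P{i:04d}"


def _layout(cfg: SimConfig) -> dict:
    """Deterministic index allocation for the planted structure.

    Shared indices (mapped in both omics) host the candidate, the
    protein-side differential features and the latent pairs; gene-only
    structure prefers the unshared index range when one exists.
    """
    shared_cursor = 1  # index 0 is the candidate
    def take_shared(k: int) -> list[int]:
        nonlocal shared_cursor
        out = list(range(shared_cursor, shared_cursor + k))
        if out and out[-1] >= cfg.n_shared_ids:
            raise ConfigError("invariant violated: planted structure does not "
                              "fit into n_shared_ids")
        shared_cursor += k
        return out

    slots = cfg.pathway_size - 1
    g_only_in_pathway = min(cfg.n_de_genes - 1, 7, slots)
    slots -= g_only_in_pathway
    p_only_in_pathway = min(cfg.n_de_proteins - 1, 7, slots)
    slots -= p_only_in_pathway
    n_null_members = slots

    prot_pathway = take_shared(p_only_in_pathway)
    extra_de_prot = take_shared(cfg.n_de_proteins - 1 - p_only_in_pathway)
    pair_idx = take_shared(cfg.n_planted_pairs - 1)

    unshared = list(range(cfg.n_shared_ids, cfg.n_genes))
    cursor = 0
    def take_gene(k: int) -> list[int]:
        nonlocal cursor, shared_cursor
        if cursor + k <= len(unshared):
            out = unshared[cursor:cursor + k]
            cursor += k
            return out
        return take_shared(k)

    gene_pathway = take_gene(g_only_in_pathway)
    extra_de_gene = take_gene(cfg.n_de_genes - 1 - g_only_in_pathway)
    null_members = take_gene(n_null_members)
    return {
        "candidate": 0,
        "prot_pathway": prot_pathway,
        "extra_de_prot": extra_de_prot,
        "pairs": pair_idx,
        "gene_pathway": gene_pathway,
        "extra_de_gene": extra_de_gene,
        "null_members": null_members,
    }


def latent_loading(cfg: SimConfig) -> float:
    """Loading on the shared latent factor that hits ``latent_rho``.

    The latent factor is centered within each group (so planted group-mean
    differences stay exact); centering shrinks its per-sample variance by
    c = (n-1)/n, and with independent log2 noise of sd sigma on both sides
    the pair correlation is a^2 c / (a^2 c + sigma^2). Solving for the
    loading: a = sigma * sqrt(rho / ((1 - rho) * c)). Zero noise gives a
    zero loading (pairs are then exactly collinear with the group design).
    """
    if cfg.noise_sd_log2 == 0 or cfg.latent_rho == 0:
        return 0.0
    if cfg.latent_rho == 1.0:
        raise ConfigError("latent_rho = 1 is unattainable with noise; "
                          "use noise_sd_log2 = 0 for exact collinearity")
    c = (cfg.n_per_group - 1) / cfg.n_per_group
    return cfg.noise_sd_log2 * float(
        np.sqrt(cfg.latent_rho / ((1.0 - cfg.latent_rho) * c))
    )


def generate_paired_omics(config: SimConfig) -> SimResult:
    """Generate the full paired-omics bundle with known planted truth.

    Two calls with identical (config, seed) produce byte-identical outputs:
    all randomness flows from a single generator state.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    lay = _layout(cfg)
    n = cfg.n_per_group
    samples = [f"FS{i+1}" for i in range(n)] + [f"PS{i+1}" for i in range(n)]
    groups = pd.Series(["FS"] * n + ["PS"] * n, index=samples)
    ps_cols = np.arange(n, 2 * n)

    gene_ids = [_gene_id(i) for i in range(cfg.n_genes)]
    protein_ids = [_protein_id(i) for i in range(cfg.n_proteins)]

    # --- signed effects -----------------------------------------------------
    def signs(k: int) -> np.ndarray:
        return np.where(rng.random(k) < _DOWN_FRACTION, -1.0, 1.0)

    de_gene_idx = [lay["candidate"]] + lay["gene_pathway"] + lay["extra_de_gene"]
    de_prot_idx = [lay["candidate"]] + lay["prot_pathway"] + lay["extra_de_prot"]
    gene_signs = np.concatenate([[-1.0], signs(len(de_gene_idx) - 1)])
    prot_signs = np.concatenate([[-1.0], signs(len(de_prot_idx) - 1)])
    de_genes = {gene_ids[i]: float(s * cfg.gene_effect_log2)
                for i, s in zip(de_gene_idx, gene_signs)}
    de_proteins = {protein_ids[i]: float(s * cfg.protein_effect_log2)
                   for i, s in zip(de_prot_idx, prot_signs)}

    # --- log2-scale abundance blocks ---------------------------------------
    base_g = rng.uniform(4.0, 10.0, cfg.n_genes)
    base_p = rng.uniform(10.0, 16.0, cfg.n_proteins)
    Lg = base_g[:, None] + rng.normal(0.0, cfg.noise_sd_log2,
                                      (cfg.n_genes, 2 * n))
    Lp = base_p[:, None] + rng.normal(0.0, cfg.noise_sd_log2,
                                      (cfg.n_proteins, 2 * n))
    for i, s in zip(de_gene_idx, gene_signs):
        Lg[i, ps_cols] += s * cfg.gene_effect_log2
    for i, s in zip(de_prot_idx, prot_signs):
        Lp[i, ps_cols] += s * cfg.protein_effect_log2

    a = latent_loading(cfg)
    z = rng.normal(0.0, 1.0, 2 * n)
    # center within each group so group means (hence log2FC) are untouched
    z[:n] -= z[:n].mean()
    z[n:] -= z[n:].mean()
    pair_idx = [lay["candidate"]] + lay["pairs"]
    # The candidate pair inherits its cross-omics correlation from the
    # shared differential response (which exceeds the target under default
    # noise); adding latent variation on top would only inflate its
    # within-group variance and mask the planted effect. The latent factor
    # therefore drives the non-differential pairs only.
    for i in lay["pairs"]:
        Lg[i] += a * z
        Lp[i] += a * z

    genes = ExpressionMatrix(
        pd.DataFrame(np.exp2(Lg), index=gene_ids, columns=samples),
        groups.copy(), unit="FPKM-like")
    proteins = ExpressionMatrix(
        pd.DataFrame(np.exp2(Lp), index=protein_ids, columns=samples),
        groups.copy(), unit="reporter-intensity-like")

    id_map = IdMap([(gene_ids[i], protein_ids[i])
                    for i in range(cfg.n_shared_ids)])

    # --- gene sets ----------------------------------------------------------
    pathway_idx = ([lay["candidate"]] + lay["gene_pathway"]
                   + lay["prot_pathway"] + lay["null_members"])
    pathway_members = [gene_ids[i] for i in sorted(pathway_idx)]
    structured = set(pathway_idx) | set(de_gene_idx) | set(de_prot_idx) \
        | set(pair_idx)
    free = np.array([i for i in range(cfg.n_genes) if i not in structured])
    sets: dict[str, tuple[str, tuple[str, ...]]] = {
        PATHWAY_NAME: ("planted co-enriched pathway",
                       tuple(pathway_members)),
    }
    decoy_size = min(cfg.pathway_size, max(2, len(free) // max(cfg.n_decoy_sets, 1)))
    for d in range(cfg.n_decoy_sets):
        if len(free) < decoy_size:
            break
        pick = rng.choice(free, size=decoy_size, replace=False)
        sets[f"decoy_{d + 1}"] = (
            "decoy set of unstructured features",
            tuple(gene_ids[i] for i in sorted(pick)))
    gene_sets = GeneSetCollection(sets)

    # --- phenotype ----------------------------------------------------------
    cand_gene = gene_ids[lay["candidate"]]
    x_cand = Lg[lay["candidate"]]
    beta = cfg.phenotype_beta
    mot = 83.0 - beta * base_g[lay["candidate"]] + beta * x_cand \
        + rng.normal(0.0, cfg.phenotype_noise_sd, 2 * n)
    via = 89.0 - beta * base_g[lay["candidate"]] + beta * x_cand \
        + rng.normal(0.0, cfg.phenotype_noise_sd, 2 * n)
    pheno = PhenotypeTable(pd.DataFrame(
        {"motility": np.clip(mot, 0.0, 100.0),
         "viability": np.clip(via, 0.0, 100.0)},
        index=pd.Index(samples, name="sample_id")))

    truth = SyntheticTruth(
        de_genes=de_genes,
        de_proteins=de_proteins,
        planted_pairs=[(gene_ids[i], protein_ids[i], cfg.latent_rho)
                       for i in pair_idx],
        pathway_name=PATHWAY_NAME,
        pathway_members=pathway_members,
        consensus_candidate=cand_gene,
        phenotype_beta=beta,
        latent_loading=a,
        config=cfg,
    )
    return SimResult(genes, proteins, id_map, gene_sets, pheno, truth)


# ---------------------------------------------------------------------------
# truth validation
# ---------------------------------------------------------------------------


@dataclass
class ValidationReport:
    checks: list[tuple[str, bool, str]] = field(default_factory=list)

    def add(self, name: str, ok: bool, detail: str = "") -> None:
        self.checks.append((name, ok, detail))

    @property
    def passed(self) -> bool:
        return all(ok for _, ok, _ in self.checks)

    def failures(self) -> list[tuple[str, str]]:
        return [(name, detail) for name, ok, detail in self.checks if not ok]


def validate_truth(result: SimResult, truth: SyntheticTruth | None = None,
                   tolerance: float = 1e-9) -> ValidationReport:
    """Check that the generated matrices actually carry the planted truth.

    Verifies per-feature realized effects (difference of group means on the
    log2 scale) against the planted signed effects within ``tolerance``,
    and the candidate's membership in every truth set. Unknown feature ids
    in the truth raise :class:`ValidationError`.
    """
    truth = truth if truth is not None else result.truth
    report = ValidationReport()
    genes, proteins = result.genes, result.proteins

    def realized(matrix: ExpressionMatrix) -> pd.Series:
        L = np.log2(matrix.data)
        fs = [s for s in matrix.sample_ids if matrix.groups[s] == "FS"]
        ps = [s for s in matrix.sample_ids if matrix.groups[s] == "PS"]
        return L[ps].mean(axis=1) - L[fs].mean(axis=1)

    eff_g = realized(genes)
    eff_p = realized(proteins)
    for fid, planted in truth.de_genes.items():
        if fid not in eff_g.index:
            raise ValidationError(f"truth names unknown gene {fid!r}")
        ok = abs(eff_g[fid] - planted) <= tolerance
        report.add(f"gene_effect:{fid}", bool(ok),
                   f"realized {eff_g[fid]:.6g} vs planted {planted:.6g}")
    for fid, planted in truth.de_proteins.items():
        if fid not in eff_p.index:
            raise ValidationError(f"truth names unknown protein {fid!r}")
        ok = abs(eff_p[fid] - planted) <= tolerance
        report.add(f"protein_effect:{fid}", bool(ok),
                   f"realized {eff_p[fid]:.6g} vs planted {planted:.6g}")

    cand = truth.consensus_candidate
    report.add("candidate_is_de_gene", cand in truth.de_genes)
    cand_prots = result.id_map.proteins_for(cand)
    report.add("candidate_mapped_protein_is_de",
               any(p in truth.de_proteins for p in cand_prots),
               f"mapped proteins: {cand_prots}")
    report.add("candidate_in_pathway", cand in truth.pathway_members)
    report.add("candidate_in_pairs",
               any(g == cand for g, _, _ in truth.planted_pairs))

    cfg = truth.config
    if cfg is not None and cfg.noise_sd_log2 > 0 and cfg.latent_rho > 0:
        # latent pairs should show the target correlation (skip at zero
        # noise where the correlation is degenerate)
        Lg = np.log2(genes.data)
        Lp = np.log2(proteins.data)
        rhos = []
        for g, p, target in truth.planted_pairs:
            if g == cand:
                continue  # candidate rho is inflated by its group effect
            r = np.corrcoef(Lg.loc[g], Lp.loc[p])[0, 1]
            rhos.append((r, target))
        if rhos:
            mean_r = float(np.mean([r for r, _ in rhos]))
            target = rhos[0][1]
            # small-sample correlations scatter widely; only a gross
            # mismatch (wrong sign / wrong regime) should fail here
            ok = abs(mean_r - target) <= max(tolerance, 0.3)
            report.add("pair_correlation", bool(ok),
                       f"mean realized rho {mean_r:.3f} vs target {target}")
    return report


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_simulation(result: SimResult, outdir: str | Path) -> dict[str, Path]:
    """Write the whole bundle (matrices, map, GMT, phenotype, truth JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genes": outdir / "genes.tsv",
        "proteins": outdir / "proteins.tsv",
        "groups": outdir / "groups.tsv",
        "id_map": outdir / "id_map.tsv",
        "gene_sets": outdir / "gene_sets.gmt",
        "phenotype": outdir / "phenotype.tsv",
        "truth": outdir / "truth.json",
    }
    write_expression_matrix(result.genes, paths["genes"])
    write_expression_matrix(result.proteins, paths["proteins"])
    result.genes.groups.to_csv(paths["groups"], sep="\t", header=False)
    write_id_map(result.id_map, paths["id_map"])
    write_gmt(result.gene_sets, paths["gene_sets"])
    write_phenotype(result.phenotype, paths["phenotype"])
    t = result.truth
    payload = {
        "de_genes": t.de_genes,
        "de_proteins": t.de_proteins,
        "planted_pairs": t.planted_pairs,
        "pathway_name": t.pathway_name,
        "pathway_members": t.pathway_members,
        "consensus_candidate": t.consensus_candidate,
        "phenotype_beta": t.phenotype_beta,
        "latent_loading": t.latent_loading,
        "config": asdict(t.config) if t.config else None,
    }
    paths["truth"].write_text(json.dumps(payload, indent=2, sort_keys=True))
    return paths
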