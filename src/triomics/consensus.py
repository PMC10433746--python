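"""Three-screen consensus: co-enrichment x Pearson network x O2PLS.

The screen builds three method-specific candidate sets in gene-symbol
space --

* ``set_kegg``: differential genes/proteins belonging to significantly
  co-enriched pathways;
* ``set_pearson``: features carrying at least one significant edge in the
  bipartite gene-protein correlation network (both endpoints count, since
  published candidate lists mix genes and proteins);
* ``set_o2pls``: features among the top-k joint loadings; by default a
  feature qualifies only when it appears in BOTH blocks' top-k lists (the
  "appeared in both the top 25 gene and protein lists" reading), with a
  union mode available --

and intersects them. A feature surviving all three screens is the
consensus candidate; the screen that motivated this package leaves exactly
one such gene. Set algebra is exact after case-insensitive id
normalization, and empty intersections are a valid outcome, not an error.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__ as _version
from .differential import (DEFAULT_ALPHA, DEFAULT_EPS, GENE_LFC_THRESHOLD,
                           PROTEIN_LFC_THRESHOLD, call_differential,
                           differential_table)
from .enrichment import CoEnrichment, co_ora
from .errors import TriomicsError
from .io import ExpressionMatrix, GeneSetCollection, IdMap
from .network import BipartiteNetwork, build_network, degree_ranking
from .o2pls import fit_o2pls, top_joint_loadings


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds and component counts for the end-to-end screen."""

    gene_lfc_threshold: float = GENE_LFC_THRESHOLD
    protein_lfc_threshold: float = PROTEIN_LFC_THRESHOLD
    alpha: float = DEFAULT_ALPHA
    eps: float = DEFAULT_EPS
    pathway_alpha: float = 0.05
    rho_threshold: float = 0.8
    corr_alpha: float = 0.05
    n_joint: int = 1
    n_orth_x: int = 0
    n_orth_y: int = 0
    top_k: int = 25
    o2pls_scale: bool = False
    o2pls_mode: str = "both_blocks"   # or "union"
    pearson_mode: str = "all_edges"   # or "top_hubs"
    top_hubs: int = 5


@dataclass
class ConsensusReport:
    """Per-method candidate sets, their intersections, and provenance."""

    set_kegg: list[str]
    set_pearson: list[str]
    set_o2pls: list[str]
    kegg_and_pearson: list[str]
    kegg_and_o2pls: list[str]
    pearson_and_o2pls: list[str]
    triple: list[str]
    provenance: dict[str, dict] = field(default_factory=dict)
    dropped_ids: list[str] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "set_kegg": self.set_kegg,
            "set_pearson": self.set_pearson,
            "set_o2pls": self.set_o2pls,
            "kegg_and_pearson": self.kegg_and_pearson,
            "kegg_and_o2pls": self.kegg_and_o2pls,
            "pearson_and_o2pls": self.pearson_and_o2pls,
            "triple": self.triple,
            "provenance": self.provenance,
            "dropped_ids": self.dropped_ids,
            "metadata": self.metadata,
        }


def _normalize(ids, id_map: IdMap | None) -> tuple[set[str], list[str]]:
    """Map mixed gene/protein ids to canonical gene-space spellings.

    Ids known to the map only as proteins are translated to their gene(s);
    everything else passes through unchanged (a gene id needs no mapping
    and an id unknown to the map cannot be told apart from one). Callers
    that know which ids are proteins should map and log them upstream
    (:func:`triomics.enrichment.co_ora` and :func:`run_pipeline` do).
    """
    out: set[str] = set()
    for f in ids:
        if id_map is not None and id_map.has_protein(f) and not id_map.has_gene(f):
            out.update(id_map.genes_for(f))
        else:
            out.add(f)
    # case-insensitive de-duplication, first spelling wins
    dedup: dict[str, str] = {}
    for f in sorted(out):
        dedup.setdefault(f.casefold(), f)
    return set(dedup.values()), []


def intersect_candidates(set_kegg, set_pearson, set_o2pls,
                         id_map: IdMap | None = None,
                         provenance: dict[str, dict] | None = None,
                         metadata: dict | None = None) -> ConsensusReport:
    """Exact set algebra over the three screens in gene space.

    Ordering in the report is lexicographic, so identical inputs always
    produce identical reports.
    """
    k, d1 = _normalize(set_kegg, id_map)
    p, d2 = _normalize(set_pearson, id_map)
    o, d3 = _normalize(set_o2pls, id_map)
    kc = {x.casefold(): x for x in k}
    pc = {x.casefold(): x for x in p}
    oc = {x.casefold(): x for x in o}
    kp = sorted(kc[c] for c in kc.keys() & pc.keys())
    ko = sorted(kc[c] for c in kc.keys() & oc.keys())
    po = sorted(pc[c] for c in pc.keys() & oc.keys())
    triple = sorted(kc[c] for c in kc.keys() & pc.keys() & oc.keys())
    prov = provenance or {}
    for c in triple:
        prov.setdefault(c, {}).setdefault(
            "screens", ["kegg", "pearson", "o2pls"])
    return ConsensusReport(
        set_kegg=sorted(k), set_pearson=sorted(p), set_o2pls=sorted(o),
        kegg_and_pearson=kp, kegg_and_o2pls=ko, pearson_and_o2pls=po,
        triple=triple, provenance=prov,
        dropped_ids=sorted(set(d1 + d2 + d3)),
        metadata=metadata or {},
    )


def rank_candidates(report: ConsensusReport) -> pd.DataFrame:
    """Order every candidate by evidence strength.

    Sort key: number of supporting screens (desc), network degree (desc),
    max |joint loading| (desc), then id. Candidates are every feature in
    any screen set.
    """
    union = set(report.set_kegg) | set(report.set_pearson) | set(report.set_o2pls)
    rows = []
    for fid in union:
        screens = sum((fid in report.set_kegg, fid in report.set_pearson,
                       fid in report.set_o2pls))
        prov = report.provenance.get(fid, {})
        rows.append((fid, screens,
                     int(prov.get("degree", 0)),
                     float(prov.get("max_abs_loading", 0.0))))
    df = pd.DataFrame(rows, columns=["feature", "n_screens", "degree",
                                     "max_abs_loading"])
    df = df.sort_values(["n_screens", "degree", "max_abs_loading", "feature"],
                        ascending=[False, False, False, True], kind="stable")
    return df.reset_index(drop=True)


@dataclass
class PipelineResult:
    report: ConsensusReport
    deg_table: pd.DataFrame
    dep_table: pd.DataFrame
    co_enrichment: CoEnrichment
    network: BipartiteNetwork
    top_loadings: dict[str, pd.DataFrame]
    o2pls_model: object


def _stage(name: str):
    """Wrap stage errors with the stage name so failures are attributable."""
    class _Ctx:
        def __enter__(self):
            return self
        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, Exception):
                raise TriomicsError(f"pipeline stage {name!r} failed: {exc}") from exc
            return False
    return _Ctx()


def run_pipeline(genes: ExpressionMatrix, proteins: ExpressionMatrix,
                 id_map: IdMap, gene_sets: GeneSetCollection,
                 config: PipelineConfig = PipelineConfig(),
                 outdir: str | Path | None = None) -> PipelineResult:
    """Execute the full screen: differential -> co-enrichment -> network ->
    O2PLS -> consensus.

    Every intermediate table is returned (and written under ``outdir`` when
    given). Empty candidate sets at any stage produce warnings and an empty
    triple intersection, never an error.
    """
    cfg = config
    with _stage("differential"):
        deg = call_differential(
            differential_table(genes, eps=cfg.eps),
            lfc_threshold=cfg.gene_lfc_threshold, alpha=cfg.alpha)
        dep = call_differential(
            differential_table(proteins, eps=cfg.eps),
            lfc_threshold=cfg.protein_lfc_threshold, alpha=cfg.alpha)

    with _stage("co_enrichment"):
        co = co_ora(deg, dep, id_map, gene_sets, alpha=cfg.pathway_alpha)
        sig_sets = co.significant_sets()
        genes_hit: set[str] = set()
        prots_hit: set[str] = set()
        for s in sig_sets:
            g, p = co.contributing(s)
            genes_hit.update(g)
            prots_hit.update(p)

    with _stage("correlation_network"):
        g_sub = genes.subset(sorted(genes_hit))
        p_sub = proteins.subset(sorted(prots_hit))
        network = build_network(g_sub, p_sub,
                                rho_threshold=cfg.rho_threshold,
                                alpha=cfg.corr_alpha, eps=cfg.eps)
        if network.edges.empty:
            warnings.warn("correlation network has no significant edges")
        if cfg.pearson_mode == "top_hubs":
            hubs = set(degree_ranking(network, cfg.top_hubs)["gene"])
            mask = network.edges["gene"].isin(hubs)
            edge_view = network.edges[mask]
        else:
            edge_view = network.edges

    with _stage("o2pls"):
        # fit on the log2 scale, consistent with the differential and
        # correlation stages (multiplicative effects become additive)
        model = fit_o2pls(genes.log2(cfg.eps).T, proteins.log2(cfg.eps).T,
                          n_joint=cfg.n_joint, n_orth_x=cfg.n_orth_x,
                          n_orth_y=cfg.n_orth_y, scale=cfg.o2pls_scale)
        top = top_joint_loadings(model, k=cfg.top_k)
        top_genes = set(top["genes"]["feature"])
        top_prots = set(top["proteins"]["feature"])
        mapped_top_prots, _drop = id_map.to_gene_space(sorted(top_prots))
        if cfg.o2pls_mode == "union":
            o2pls_ids = top_genes | mapped_top_prots
        else:  # present in BOTH blocks' top-k lists
            gene_space_genes = {g.casefold() for g in top_genes}
            o2pls_ids = {g for g in mapped_top_prots
                         if g.casefold() in gene_space_genes}

    with _stage("consensus"):
        provenance: dict[str, dict] = {}
        deg_of = network.degree_of

        def note(fid_gene_space: set[str], screen: str, extras=None):
            for f in fid_gene_space:
                entry = provenance.setdefault(f, {"screens": []})
                if screen not in entry["screens"]:
                    entry["screens"].append(screen)
                if extras:
                    entry.update(extras(f))

        # gene ids pass through; protein ids translate via the map
        mapped_prots_hit, drop_k = id_map.to_gene_space(sorted(prots_hit))
        kegg_gene_space = set(genes_hit) | mapped_prots_hit
        mapped_edge_prots, drop_p = id_map.to_gene_space(
            sorted(set(edge_view["protein"])))
        pearson_gene_space = set(edge_view["gene"]) | mapped_edge_prots
        note(kegg_gene_space, "kegg",
             lambda f: {"pathways": [s for s in sig_sets
                                     if f in co.contributing(s)[0]
                                     or any(f in id_map.genes_for(p)
                                            for p in co.contributing(s)[1])]})
        note(pearson_gene_space, "pearson",
             lambda f: {"degree": max(
                 [deg_of.get(f, 0)]
                 + [deg_of.get(p, 0) for p in id_map.proteins_for(f)])})
        abs_by_gene = {}
        for f in (top_genes | top_prots):
            for g in ([f] if id_map.has_gene(f) else id_map.genes_for(f)):
                block = "genes" if id_map.has_gene(f) else "proteins"
                tbl = top["genes" if block == "genes" else "proteins"]
                row = tbl[tbl["feature"] == f]
                if len(row):
                    v = float(row["abs_loading"].iloc[0])
                    abs_by_gene[g] = max(abs_by_gene.get(g, 0.0), v)
        note(o2pls_ids, "o2pls",
             lambda f: {"max_abs_loading": abs_by_gene.get(f, 0.0)})

        metadata = {
            "thresholds": {
                "gene_lfc": cfg.gene_lfc_threshold,
                "protein_lfc": cfg.protein_lfc_threshold,
                "alpha": cfg.alpha,
                "pathway_alpha": cfg.pathway_alpha,
                "rho_threshold": cfg.rho_threshold,
                "corr_alpha": cfg.corr_alpha,
                "top_k": cfg.top_k,
            },
            "o2pls": {"n_joint": cfg.n_joint, "n_orth_x": cfg.n_orth_x,
                      "n_orth_y": cfg.n_orth_y, "scale": cfg.o2pls_scale,
                      "mode": cfg.o2pls_mode},
            "pearson_mode": cfg.pearson_mode,
            "significant_pathways": sig_sets,
            "n_deg": int((deg["call"] != "ns").sum()),
            "n_dep": int((dep["call"] != "ns").sum()),
            "version": _version,
            "unmapped_protein_ids": sorted(set(drop_k + drop_p)),
        }
        report = intersect_candidates(kegg_gene_space, pearson_gene_space,
                                      o2pls_ids, id_map=id_map,
                                      provenance=provenance,
                                      metadata=metadata)
        # internal consistency: triple must equal (K ^ P) ^ O
        kp = set(report.kegg_and_pearson)
        assert set(report.triple) == kp & set(report.set_o2pls)

    result = PipelineResult(report=report, deg_table=deg, dep_table=dep,
                            co_enrichment=co, network=network,
                            top_loadings=top, o2pls_model=model)
    if outdir is not None:
        _write_outputs(result, Path(outdir))
    return result


def _write_outputs(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.deg_table.to_csv(outdir / "deg_table.tsv", sep="\t",
                            index_label="feature_id")
    result.dep_table.to_csv(outdir / "dep_table.tsv", sep="\t",
                            index_label="feature_id")
    result.co_enrichment.table.to_csv(outdir / "co_enrichment.tsv", sep="\t",
                                      index=False)
    result.network.edges.to_csv(outdir / "network_edges.tsv", sep="\t",
                                index=False)
    degree_ranking(result.network, top_n=len(result.network.gene_nodes) or 1
                   ).to_csv(outdir / "degree_ranking.tsv", sep="\t", index=False)
    result.top_loadings["genes"].to_csv(outdir / "o2pls_top_genes.tsv",
                                        sep="\t", index=False)
    result.top_loadings["proteins"].to_csv(outdir / "o2pls_top_proteins.tsv",
                                           sep="\t", index=False)
    (outdir / "consensus_report.json").write_text(
        json.dumps(result.report.to_dict(), indent=2, sort_keys=True))
    rank_candidates(result.report).to_csv(outdir / "candidate_ranking.tsv",
                                          sep="\t", index=False)
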