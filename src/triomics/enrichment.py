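"""Over-representation analysis, cross-omics co-enrichment, and GSEA.

ORA is the exact hypergeometric upper tail: with a universe of N features,
K of them in a pathway, and a selection of n features hitting k pathway
members, p = P(X >= k) for X ~ Hypergeom(N, K, n). Co-enrichment runs the
same test on the gene-space union of differential genes and (id-mapped)
differential proteins, and reports which omics contributed each hit.

GSEA is the weighted Kolmogorov-Smirnov running sum over a ranked feature
list: walking down the ranking, the sum rises by |score|^weight (normalized
over set members) at each member and falls by 1/(N-K) otherwise; the
enrichment score is the extremum. Significance comes from a feature-label
permutation null -- with three samples per group a phenotype-permutation
null has only 20 distinct relabelings, far too few, so set membership is
permuted instead (recorded in the result metadata).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .differential import bh_adjust, called_features
from .errors import DomainError
from .io import GeneSetCollection, IdMap


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeom(population N, successes K, draws n)."""
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k):
        raise DomainError("require 0 <= K,n <= N and k >= 0")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def ora(selected, universe, sets: GeneSetCollection) -> pd.DataFrame:
    """Hypergeometric over-representation of ``selected`` within ``universe``.

    Each set is intersected with the universe before testing. Returns a
    DataFrame sorted by p with columns set_name, k, K, n, N, p_hyper, fdr,
    members_hit; BH adjustment runs across the tested sets.
    """
    universe = list(dict.fromkeys(universe))
    uni = set(universe)
    selected = list(dict.fromkeys(selected))
    offenders = [s for s in selected if s not in uni]
    if offenders:
        raise DomainError(f"selected features outside the universe: {offenders}")
    sel = set(selected)
    N, n = len(uni), len(sel)
    rows = []
    for name in sets.names():
        members = set(sets.members(name)) & uni
        K = len(members)
        hit = sorted(members & sel)
        k = len(hit)
        p = hypergeom_upper_tail(k, K, n, N) if K else 1.0
        rows.append((name, k, K, n, N, p, ",".join(hit)))
    out = pd.DataFrame(rows, columns=["set_name", "k", "K", "n", "N",
                                      "p_hyper", "members_hit"])
    out["fdr"] = bh_adjust(out["p_hyper"].to_numpy()) if len(out) else []
    out = out.sort_values(["p_hyper", "set_name"], kind="stable")
    return out.reset_index(drop=True)[
        ["set_name", "k", "K", "n", "N", "p_hyper", "fdr", "members_hit"]
    ]


@dataclass
class CoEnrichment:
    """Cross-omics co-enrichment outcome.

    ``table`` has one row per set with the hypergeometric test on the
    combined gene-space selection plus per-omics contributor columns;
    ``dropped_proteins`` logs differential proteins without an id-map entry
    (excluded, never silently discarded).
    """

    table: pd.DataFrame
    selection: set[str]
    universe: set[str]
    dropped_proteins: list[str] = field(default_factory=list)
    alpha: float = 0.05

    def significant_sets(self) -> list[str]:
        t = self.table
        return list(t.loc[t["p_hyper"] < self.alpha, "set_name"])

    def contributing(self, set_name: str) -> tuple[list[str], list[str]]:
        row = self.table.set_index("set_name").loc[set_name]
        genes = row["genes_hit"].split(",") if row["genes_hit"] else []
        prots = row["proteins_hit"].split(",") if row["proteins_hit"] else []
        return genes, prots


def co_ora(deg_table: pd.DataFrame, dep_table: pd.DataFrame, id_map: IdMap,
           sets: GeneSetCollection, alpha: float = 0.05) -> CoEnrichment:
    """Co-enrichment over the union of differential genes and proteins.

    The selection is the gene-space union of called genes and id-mapped
    called proteins; the universe is the union of both quantified spaces in
    gene space. Significance is reported at raw p < alpha (the convention
    for combined-omics pathway lists), with a BH column alongside.
    """
    degs = called_features(deg_table)
    deps = called_features(dep_table)
    mapped_deps, dropped = id_map.to_gene_space(deps)
    # mapped_deps may contain gene ids from the map; keep DEGs verbatim.
    prot_uni_mapped, dropped_uni = id_map.to_gene_space(list(dep_table.index))
    universe = set(deg_table.index) | prot_uni_mapped
    selection = set(degs) | mapped_deps
    if not selection:
        warnings.warn("empty DEG/DEP union; co-enrichment result is empty")
    base = ora(sorted(selection), sorted(universe), sets)
    # attribute each hit to its omics of origin
    deg_set = set(degs)
    genes_hit_col, prots_hit_col = [], []
    prot_by_gene: dict[str, list[str]] = {}
    for p in deps:
        for g in id_map.genes_for(p):
            prot_by_gene.setdefault(g, []).append(p)
    for _, row in base.iterrows():
        hits = row["members_hit"].split(",") if row["members_hit"] else []
        genes_hit_col.append(",".join(h for h in hits if h in deg_set))
        prots = [p for h in hits for p in prot_by_gene.get(h, [])]
        prots_hit_col.append(",".join(sorted(set(prots))))
    table = base.copy()
    table["genes_hit"] = genes_hit_col
    table["proteins_hit"] = prots_hit_col
    table["significant"] = table["p_hyper"] < alpha
    return CoEnrichment(table=table, selection=selection, universe=universe,
                        dropped_proteins=sorted(set(dropped)), alpha=alpha)


# ---------------------------------------------------------------------------
# GSEA
# ---------------------------------------------------------------------------


def _order_ranking(ranking: pd.Series) -> pd.Series:
    """Descending by score, ties broken by feature id (deterministic)."""
    df = pd.DataFrame({"score": ranking.astype(float)})
    df["fid"] = df.index.astype(str)
    df = df.sort_values(["score", "fid"], ascending=[False, True],
                        kind="stable")
    return df["score"]


def _es_core(abs_scores_w: np.ndarray, hit: np.ndarray) -> tuple[float, int]:
    """Running-sum extremum for a pre-sorted ranking.

    ``abs_scores_w`` holds |score|^weight in ranking order; ``hit`` marks
    set members. Returns (ES, extremum position).
    """
    N = hit.shape[0]
    K = int(hit.sum())
    w = np.where(hit, abs_scores_w, 0.0)
    total = w.sum()
    if total == 0:  # all member scores exactly zero: fall back to equal steps
        w = hit.astype(float)
        total = float(K)
    step = w / total
    if N > K:
        step = step - np.where(hit, 0.0, 1.0 / (N - K))
    running = np.cumsum(step)
    peak = int(np.argmax(np.abs(running)))
    return float(running[peak]), peak


def enrichment_score(ranking: pd.Series, members, weight: float = 1.0
                     ) -> tuple[float, list[str]]:
    """Weighted KS running-sum enrichment score and leading edge.

    ``ranking`` maps feature id -> score; it is re-sorted internally so the
    caller need not pre-sort. Members absent from the ranking are ignored.
    """
    ordered = _order_ranking(ranking)
    ids = np.asarray(ordered.index, dtype=object)
    scores = ordered.to_numpy()
    member_set = set(members)
    hit = np.fromiter((f in member_set for f in ids), dtype=bool, count=len(ids))
    if not hit.any():
        raise DomainError("gene set has no overlap with the ranking")
    es, peak = _es_core(np.abs(scores) ** weight, hit)
    if es >= 0:
        leading = [str(f) for f, h in zip(ids[: peak + 1], hit[: peak + 1]) if h]
    else:
        leading = [str(f) for f, h in zip(ids[peak:], hit[peak:]) if h]
    return es, leading


def gsea(ranking: pd.Series, sets: GeneSetCollection, n_perm: int = 999,
         weight: float = 1.0, seed: int | None = None) -> pd.DataFrame:
    """GSEA over a ranked feature list with a set-label permutation null.

    Returns a DataFrame with set_name, es, nes, p_perm, k, leading_edge.
    ``p_perm`` uses add-one smoothing, (1 + #{null at least as extreme,
    same sign}) / (n_perm + 1), so it is never zero. Sets with no overlap
    are skipped with a warning.
    """
    if ranking.index.duplicated().any():
        raise DomainError("ranking has duplicate feature ids")
    if n_perm < 100:
        raise DomainError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    ordered = _order_ranking(ranking)
    ids = list(ordered.index)
    N = len(ids)
    abs_w = np.abs(ordered.to_numpy()) ** weight
    rows = []
    for name in sets.names():
        members = set(sets.members(name)) & set(ids)
        if not members:
            warnings.warn(f"set {name!r} has no overlap with the ranking; skipped")
            continue
        es, leading = enrichment_score(ordered, members, weight=weight)
        K = len(members)
        null = np.empty(n_perm)
        mask = np.zeros(N, dtype=bool)
        for i in range(n_perm):
            idx = rng.choice(N, size=K, replace=False)
            mask[:] = False
            mask[idx] = True
            null[i], _ = _es_core(abs_w, mask)
        same_sign = null[null >= 0] if es >= 0 else null[null <= 0]
        if es >= 0:
            extreme = int((null >= es).sum())
        else:
            extreme = int((null <= es).sum())
        p = (1 + extreme) / (n_perm + 1)
        denom = np.abs(same_sign).mean() if len(same_sign) else np.abs(null).mean()
        nes = es / denom if denom > 0 else np.nan
        rows.append((name, es, float(nes), float(p), K, ",".join(leading)))
    out = pd.DataFrame(rows, columns=["set_name", "es", "nes", "p_perm", "k",
                                      "leading_edge"])
    out = out.sort_values(["p_perm", "set_name"], kind="stable")
    out.attrs["null"] = "gene_set_label_permutation"
    out.attrs["n_perm"] = n_perm
    out.attrs["weight"] = weight
    return out.reset_index(drop=True)
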