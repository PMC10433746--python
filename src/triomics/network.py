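"""Bipartite gene-protein Pearson correlation network.

Every pathway-enriched differential gene is correlated with every
pathway-enriched differential protein across the matched samples (fresh and
frozen pooled -- the design is paired, so each sample contributes one
transcript and one protein measurement). An edge is kept when |rho| exceeds
the threshold AND the two-sided p-value clears alpha; the published gate is
|rho| > 0.8 with p < 0.05 and no multiple-testing correction (an optional
BH mode exists). Degree ranking over the surviving edges identifies hub
genes; the same Pearson machinery serves candidate-vs-phenotype checks.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .differential import bh_adjust
from .errors import AlignmentError, DomainError
from .io import ExpressionMatrix


def pearson(x, y) -> tuple[float, float]:
    """Sample Pearson rho with the two-sided p from the t-transform.

    p comes from t = rho * sqrt((n-2)/(1-rho^2)) on n-2 degrees of freedom
    (scipy's exact beta form is identical); exact |rho| = 1 gives p = 0.
    Zero variance in either vector is an error, not rho = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError("x and y must be equal-length 1-D vectors")
    if len(x) < 3:
        raise DomainError("need at least 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DomainError("undefined correlation: zero variance input")
    r, p = stats.pearsonr(x, y)
    if abs(r) >= 1.0 - 1e-14:  # exact (anti)linearity
        return float(np.sign(r)), 0.0
    return float(r), float(p)


@dataclass
class BipartiteNetwork:
    """Significant gene-protein correlation edges plus degree bookkeeping."""

    gene_nodes: list[str]
    protein_nodes: list[str]
    edges: pd.DataFrame  # columns: gene, protein, rho, p
    dropped: list[tuple[str, str, str]] = field(default_factory=list)
    rho_threshold: float = 0.8
    alpha: float = 0.05

    @property
    def degree_of(self) -> dict[str, int]:
        deg = Counter()
        deg.update({g: 0 for g in self.gene_nodes})
        deg.update({p: 0 for p in self.protein_nodes})
        for _, row in self.edges.iterrows():
            deg[row["gene"]] += 1
            deg[row["protein"]] += 1
        return dict(deg)

    def neighbors(self, node: str) -> list[str]:
        e = self.edges
        out = list(e.loc[e["gene"] == node, "protein"])
        out += list(e.loc[e["protein"] == node, "gene"])
        return sorted(out)


def _row_correlations(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """All-pairs Pearson rho between rows of A and rows of B (same columns)."""
    n = A.shape[1]
    Az = A - A.mean(axis=1, keepdims=True)
    Bz = B - B.mean(axis=1, keepdims=True)
    sa = np.sqrt((Az**2).sum(axis=1))
    sb = np.sqrt((Bz**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        R = (Az @ Bz.T) / np.outer(sa, sb)
    return np.clip(R, -1.0, 1.0)


def build_network(genes: ExpressionMatrix, proteins: ExpressionMatrix,
                  rho_threshold: float = 0.8, alpha: float = 0.05,
                  log_scale: bool = True, eps: float = 1e-3,
                  bh: bool = False) -> BipartiteNetwork:
    """Test every gene x protein pair and keep the significant edges.

    Both matrices must carry the same samples in the same order (paired
    design). Abundances are log2-transformed by default, matching the scale
    the differential statistics use. Zero-variance features cannot have a
    defined correlation and are logged as dropped. ``bh=True`` swaps the
    raw-p gate for a BH-adjusted one (off by default).
    """
    if genes.sample_ids != proteins.sample_ids:
        raise AlignmentError(
            "gene and protein matrices must share sample order: "
            f"{genes.sample_ids} vs {proteins.sample_ids}"
        )
    n = len(genes.sample_ids)
    if n < 3:
        raise DomainError("need at least 3 samples for correlation")
    G = genes.log2(eps).to_numpy() if log_scale else genes.values.astype(float)
    P = proteins.log2(eps).to_numpy() if log_scale else proteins.values.astype(float)
    g_ids = genes.feature_ids
    p_ids = proteins.feature_ids
    dropped: list[tuple[str, str, str]] = []
    g_ok = np.std(G, axis=1) > 0
    p_ok = np.std(P, axis=1) > 0
    for gi in np.flatnonzero(~g_ok):
        dropped.append((g_ids[gi], "*", "zero variance gene"))
    for pi in np.flatnonzero(~p_ok):
        dropped.append(("*", p_ids[pi], "zero variance protein"))
    rows = []
    if g_ok.any() and p_ok.any():
        R = _row_correlations(G[g_ok], P[p_ok])
        df = n - 2
        with np.errstate(divide="ignore"):
            t = np.abs(R) * np.sqrt(df / (1.0 - R**2))
        pvals = 2 * stats.t.sf(t, df)
        pvals[np.abs(R) >= 1.0 - 1e-14] = 0.0
        if bh:
            pvals = bh_adjust(pvals.ravel()).reshape(pvals.shape)
        gi_idx = np.flatnonzero(g_ok)
        pi_idx = np.flatnonzero(p_ok)
        for a, gi in enumerate(gi_idx):
            for b, pi in enumerate(pi_idx):
                if abs(R[a, b]) > rho_threshold and pvals[a, b] < alpha:
                    rows.append((g_ids[gi], p_ids[pi],
                                 float(R[a, b]), float(pvals[a, b])))
                else:
                    dropped.append((g_ids[gi], p_ids[pi], "below threshold"))
    edges = pd.DataFrame(rows, columns=["gene", "protein", "rho", "p"])
    edges = edges.sort_values(["gene", "protein"], kind="stable").reset_index(drop=True)
    return BipartiteNetwork(gene_nodes=list(g_ids), protein_nodes=list(p_ids),
                            edges=edges, dropped=dropped,
                            rho_threshold=rho_threshold, alpha=alpha)


def degree_ranking(network: BipartiteNetwork, top_n: int = 5) -> pd.DataFrame:
    """Gene nodes ordered by edge count (desc), ties lexicographic.

    ``top_n=5`` mirrors the usual hub-gene shortlist; genes without edges
    are not listed.
    """
    deg = network.degree_of
    ranked = sorted(((g, deg[g]) for g in network.gene_nodes if deg[g] > 0),
                    key=lambda t: (-t[1], t[0]))
    return pd.DataFrame(ranked[:top_n], columns=["gene", "degree"])


def phenotype_correlation(abundance: pd.Series, phenotype: pd.Series
                          ) -> tuple[float, float]:
    """Pearson rho between a feature's per-sample abundance and a phenotype.

    Samples are aligned by id; at least 3 shared samples are required.
    """
    shared = [s for s in abundance.index if s in phenotype.index]
    if len(shared) < 3:
        raise DomainError("need at least 3 samples shared with the phenotype")
    return pearson(abundance.loc[shared].to_numpy(),
                   phenotype.loc[shared].to_numpy())
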