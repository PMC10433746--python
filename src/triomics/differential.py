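"""Per-feature differential statistics and threshold calling.

The screen uses the classical small-sample recipe: a pooled-variance
(Student's) two-sample t-test per feature on log2-transformed abundance,
Benjamini-Hochberg adjustment across features, and a strict fold-change +
FDR gate. Fold change is oriented frozen-over-fresh (PS/FS), so "down"
means reduced after cryopreservation.

Default gates follow the field convention for the two omics layers:
|log2FC| > 1 for transcripts and |log2FC| > 0.263 (a 1.2x ratio) for TMT
protein abundances, both at FDR < 0.05, with strict inequalities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DomainError
from .io import GROUP_FRESH, GROUP_FROZEN, ExpressionMatrix

GENE_LFC_THRESHOLD = 1.0
PROTEIN_LFC_THRESHOLD = 0.263
DEFAULT_ALPHA = 0.05
DEFAULT_EPS = 1e-3


@dataclass(frozen=True)
class TestResult:
    """Two-sample t-test outcome: statistic, degrees of freedom, p, and a
    flag marking zero-pooled-variance degeneracy (p set by convention)."""

    t: float
    df: float
    p_two_sided: float
    degenerate: bool = False


def _pooled_t(m1: float, v1: float, n1: int, m2: float, v2: float, n2: int
              ) -> TestResult:
    """Pooled-variance t with the degenerate conventions.

    Zero pooled variance with equal means -> t=0, p=1; with unequal means
    -> p=0 (flagged). Both are reported rather than dropped so downstream
    calling still sees every feature.
    """
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    if sp2 <= 0:
        if m1 == m2:
            return TestResult(0.0, df, 1.0, degenerate=True)
        t = np.inf if m1 > m2 else -np.inf
        return TestResult(float(t), df, 0.0, degenerate=True)
    se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
    t = (m1 - m2) / se
    p = 2 * stats.t.sf(abs(t), df)
    return TestResult(float(t), float(df), float(p))


def log2_fold_change(matrix: ExpressionMatrix, eps: float = DEFAULT_EPS
                     ) -> pd.Series:
    """Per-feature log2((mean_PS + eps)/(mean_FS + eps)).

    The pseudocount keeps features that drop to (near) zero in one group
    finite; such features produce the very large |log2FC| magnitudes
    (around +/-11 for an eps of 1e-3 against abundances in the thousands)
    familiar from transcript tables.
    """
    if eps <= 0:
        raise DomainError("eps must be > 0")
    fs = matrix.group_data(GROUP_FRESH)
    ps = matrix.group_data(GROUP_FROZEN)
    if fs.shape[1] == 0 or ps.shape[1] == 0:
        raise DomainError("both FS and PS groups must be non-empty")
    lfc = np.log2(ps.mean(axis=1) + eps) - np.log2(fs.mean(axis=1) + eps)
    lfc.name = "log2fc"
    return lfc


def student_t_test(matrix: ExpressionMatrix, eps: float = DEFAULT_EPS,
                   log_transform: bool = True, welch: bool = False
                   ) -> pd.DataFrame:
    """Per-feature two-sample t-test, PS minus FS, on log2 abundance.

    Returns a DataFrame indexed by feature with columns ``t``, ``df``,
    ``p``, ``degenerate``. ``welch=True`` switches to the unequal-variance
    form; the pooled (Student's) form is the default.
    """
    fs_ids = matrix.samples_in_group(GROUP_FRESH)
    ps_ids = matrix.samples_in_group(GROUP_FROZEN)
    if len(fs_ids) < 2 or len(ps_ids) < 2:
        raise DomainError("need >=2 samples per group for a t-test")
    data = matrix.log2(eps) if log_transform else matrix.data
    a = data[ps_ids].to_numpy(dtype=float)  # group 1 = PS
    b = data[fs_ids].to_numpy(dtype=float)
    n1, n2 = a.shape[1], b.shape[1]
    rows = []
    if welch:
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
        for ti, pi, di in zip(np.atleast_1d(res.statistic),
                              np.atleast_1d(res.pvalue),
                              np.atleast_1d(res.df)):
            degen = not np.isfinite(ti)
            rows.append((float(ti), float(di), float(pi), degen))
    else:
        m1, m2 = a.mean(axis=1), b.mean(axis=1)
        v1 = a.var(axis=1, ddof=1)
        v2 = b.var(axis=1, ddof=1)
        for i in range(len(m1)):
            r = _pooled_t(m1[i], v1[i], n1, m2[i], v2[i], n2)
            rows.append((r.t, r.df, r.p_two_sided, r.degenerate))
    out = pd.DataFrame(rows, index=data.index,
                       columns=["t", "df", "p", "degenerate"])
    return out


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1).

    Step-up means p_(i) * m / i with a cumulative minimum taken from the
    largest rank downward; tied p-values share the adjusted value of their
    common rank position. Delegates to statsmodels' ``fdr_bh``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise DomainError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_table(matrix: ExpressionMatrix, eps: float = DEFAULT_EPS,
                       log_transform: bool = True, welch: bool = False
                       ) -> pd.DataFrame:
    """Combine fold change, t-test and BH adjustment into one table.

    Columns: ``log2fc``, ``t``, ``df``, ``p``, ``fdr``, ``degenerate``.
    The transform used for the test is recorded in ``DataFrame.attrs`` so
    output files are self-describing.
    """
    lfc = log2_fold_change(matrix, eps=eps)
    tt = student_t_test(matrix, eps=eps, log_transform=log_transform,
                        welch=welch)
    table = tt.copy()
    table.insert(0, "log2fc", lfc)
    table["fdr"] = bh_adjust(table["p"].to_numpy())
    table.attrs["test"] = "welch" if welch else "student_pooled"
    table.attrs["scale"] = (f"log2(abundance + {eps})" if log_transform
                            else "abundance")
    table.attrs["orientation"] = "PS_over_FS"
    return table


def call_differential(table: pd.DataFrame,
                      lfc_threshold: float = GENE_LFC_THRESHOLD,
                      alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Apply the strict |log2FC| > threshold AND fdr < alpha gate.

    Adds a ``call`` column in {"up", "down", "ns"}; up/down counts land in
    ``DataFrame.attrs``. Features exactly at either boundary are ``ns``.
    """
    out = table.copy()
    sig = (out["log2fc"].abs() > lfc_threshold) & (out["fdr"] < alpha)
    out["call"] = np.where(sig & (out["log2fc"] > 0), "up",
                           np.where(sig, "down", "ns"))
    out.attrs.update(table.attrs)
    out.attrs["lfc_threshold"] = lfc_threshold
    out.attrs["alpha"] = alpha
    out.attrs["n_up"] = int((out["call"] == "up").sum())
    out.attrs["n_down"] = int((out["call"] == "down").sum())
    return out


def called_features(table: pd.DataFrame) -> list[str]:
    """Feature ids with a non-"ns" call, in table order."""
    return list(table.index[table["call"] != "ns"])


def ttest_from_summary(mean1: float, sem1: float, n1: int,
                       mean2: float, sem2: float, n2: int) -> TestResult:
    """Pooled-variance two-sample t-test reconstructed from mean +/- SEM.

    Summary tables report mean +/- SEM per group; sd is recovered as
    SEM * sqrt(n). Useful for checking published group comparisons (e.g.
    motility 82.63 +/- 3.55 vs 34.10 +/- 2.90 at n=3/3 gives p < 0.001).
    """
    if n1 < 2 or n2 < 2:
        raise DomainError("need n >= 2 per group")
    if sem1 < 0 or sem2 < 0:
        raise DomainError("SEMs must be non-negative")
    v1 = (sem1 * np.sqrt(n1)) ** 2
    v2 = (sem2 * np.sqrt(n2)) ** 2
    return _pooled_t(mean1, v1, n1, mean2, v2, n2)
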