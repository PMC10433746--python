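"""Two-way orthogonal PLS (O2PLS) on paired omics blocks.

O2PLS decomposes two sample-matched blocks X (samples x genes) and Y
(samples x proteins) into joint variation shared between the blocks,
structured variation orthogonal to the other block, and residual noise:

    X = T W' + T_orth P_orth' + E,    Y = U C' + U_orth Q_orth' + F

The joint loadings W and C come from the singular value decomposition of
the cross-covariance matrix X'Y; block-specific ("orthogonal") components
are estimated from what the joint projection leaves behind and deflated
out, after which the joint part is re-fit. Features with large |joint
loading| drive the shared gene-protein covariation and are the integration
candidates; the conventional shortlist is the top 25 per block.

With six samples only one joint component is realistically identifiable,
so the defaults are one joint and zero orthogonal components; the counts
are configurable and echoed in the model metadata. Columns are centered
before fitting (unit-variance scaling optional). Loading signs are fixed
deterministically: the largest-magnitude entry of each loading column is
made positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlignmentError, DomainError, RankError


def _as_frame(block, prefix: str) -> pd.DataFrame:
    if isinstance(block, pd.DataFrame):
        return block.astype(float)
    arr = np.asarray(block, dtype=float)
    return pd.DataFrame(arr, columns=[f"{prefix}{j}" for j in range(arr.shape[1])])


def _fix_signs(W: np.ndarray, *followers: np.ndarray) -> None:
    """Flip each loading column so its largest-|.| element is positive.

    ``followers`` (e.g. the matching score matrix) are flipped in lockstep
    so the reconstruction is unchanged.
    """
    for j in range(W.shape[1]):
        col = W[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            W[:, j] = -col
            for F in followers:
                F[:, j] = -F[:, j]


@dataclass
class O2plsModel:
    """Fitted O2PLS decomposition.

    Loadings are DataFrames indexed by feature; scores are samples x
    components. ``B_t``/``B_u`` are the scalar inner-relation coefficients
    per joint component (U ~ T B_t and T ~ U B_u).
    """

    W: pd.DataFrame               # gene-block joint loadings
    C: pd.DataFrame               # protein-block joint loadings
    T: np.ndarray                 # gene-block joint scores
    U: np.ndarray                 # protein-block joint scores
    W_orth: pd.DataFrame
    P_orth: pd.DataFrame
    T_orth: np.ndarray
    C_orth: pd.DataFrame
    Q_orth: pd.DataFrame
    U_orth: np.ndarray
    B_t: np.ndarray
    B_u: np.ndarray
    x_mean: pd.Series
    y_mean: pd.Series
    x_scale: pd.Series | None
    y_scale: pd.Series | None
    n_joint: int
    n_orth_x: int
    n_orth_y: int
    metadata: dict = field(default_factory=dict)


def _preprocess(F: pd.DataFrame, scale: bool):
    mean = F.mean(axis=0)
    Z = F - mean
    sd = None
    if scale:
        sd = F.std(axis=0, ddof=1)
        if (sd == 0).any():
            raise DomainError("unit-variance scaling undefined for "
                              "zero-variance feature(s)")
        Z = Z / sd
    return Z.to_numpy(), mean, sd


def _joint_svd(Xc: np.ndarray, Yc: np.ndarray, a: int):
    Uv, s, Vt = np.linalg.svd(Xc.T @ Yc, full_matrices=False)
    if a > len(s) or s[a - 1] <= max(Xc.shape + Yc.shape) * 1e-14 * (s[0] if len(s) else 1.0):
        raise RankError(
            f"requested {a} joint component(s) but the cross-covariance has "
            f"rank < {a}"
        )
    return Uv[:, :a].copy(), Vt[:a].T.copy()


def fit_o2pls(X, Y, n_joint: int = 1, n_orth_x: int = 0, n_orth_y: int = 0,
              scale: bool = False) -> O2plsModel:
    """Fit O2PLS to paired blocks (rows = matched samples).

    ``X`` and ``Y`` are samples x features DataFrames (or arrays) with
    identical row order. ``n_joint`` joint components are taken from the
    SVD of the centered cross-covariance; ``n_orth_x``/``n_orth_y``
    block-orthogonal components are deflated from each block before the
    joint part is re-fit.
    """
    Xf = _as_frame(X, "x")
    Yf = _as_frame(Y, "y")
    if Xf.shape[0] != Yf.shape[0]:
        raise AlignmentError("X and Y must have the same number of samples")
    if isinstance(X, pd.DataFrame) and isinstance(Y, pd.DataFrame):
        if list(Xf.index) != list(Yf.index):
            raise AlignmentError("X and Y must carry the same samples in the "
                                 "same order")
    n = Xf.shape[0]
    if n_joint < 1:
        raise DomainError("n_joint must be >= 1")
    if n_joint + max(n_orth_x, n_orth_y) >= n:
        raise RankError("n_joint plus orthogonal components must be smaller "
                        f"than the number of samples ({n})")
    Xc, x_mean, x_sd = _preprocess(Xf, scale)
    Yc, y_mean, y_sd = _preprocess(Yf, scale)
    if not Xc.any() or not Yc.any():
        raise DomainError("a block has no variance to decompose")

    cross_joint_cov: list[float] = []

    def orth_deflate(Zc: np.ndarray, other: np.ndarray, k: int):
        """Remove k components of Zc's structured variation not shared
        with ``other`` (the classic E'T construction).

        Each extracted score is, by construction, exactly uncorrelated
        with the opposite block's joint scores as estimated at extraction
        time (w_o lies outside the joint loading span, so w_o'Z'OC = 0);
        the realized covariances are recorded as a diagnostic.
        """
        W_o = np.empty((Zc.shape[1], k))
        P_o = np.empty((Zc.shape[1], k))
        T_o = np.empty((Zc.shape[0], k))
        for i in range(k):
            W_joint, C_joint = _joint_svd(Zc, other, n_joint)
            Tj = Zc @ W_joint
            E = Zc - Tj @ W_joint.T
            u, s, _ = np.linalg.svd(E.T @ Tj, full_matrices=False)
            if s[0] <= 1e-12:
                raise RankError("no orthogonal variation left to extract")
            w = u[:, 0]
            t = Zc @ w
            opp = other @ C_joint  # opposite block's joint scores, current
            denom = np.linalg.norm(t) * np.linalg.norm(opp, axis=0).max()
            cross_joint_cov.append(float(np.abs(t @ opp).max() / max(denom, 1e-300)))
            p = Zc.T @ t / (t @ t)
            Zc = Zc - np.outer(t, p)
            W_o[:, i], P_o[:, i], T_o[:, i] = w, p, t
        return Zc, W_o, P_o, T_o

    if n_orth_x:
        Xc, W_o, P_o, T_o = orth_deflate(Xc, Yc, n_orth_x)
    else:
        W_o = np.empty((Xc.shape[1], 0)); P_o = np.empty((Xc.shape[1], 0))
        T_o = np.empty((n, 0))
    if n_orth_y:
        Yc, C_o, Q_o, U_o = orth_deflate(Yc, Xc, n_orth_y)
    else:
        C_o = np.empty((Yc.shape[1], 0)); Q_o = np.empty((Yc.shape[1], 0))
        U_o = np.empty((n, 0))

    W, C = _joint_svd(Xc, Yc, n_joint)
    T = Xc @ W
    U = Yc @ C
    _fix_signs(W, T)
    _fix_signs(C, U)
    B_t = np.array([(T[:, j] @ U[:, j]) / (T[:, j] @ T[:, j])
                    for j in range(n_joint)])
    B_u = np.array([(T[:, j] @ U[:, j]) / (U[:, j] @ U[:, j])
                    for j in range(n_joint)])
    _fix_signs(W_o, T_o, P_o)
    _fix_signs(C_o, U_o, Q_o)

    jcols = [f"joint{j + 1}" for j in range(n_joint)]
    model = O2plsModel(
        W=pd.DataFrame(W, index=Xf.columns, columns=jcols),
        C=pd.DataFrame(C, index=Yf.columns, columns=jcols),
        T=T, U=U,
        W_orth=pd.DataFrame(W_o, index=Xf.columns),
        P_orth=pd.DataFrame(P_o, index=Xf.columns),
        T_orth=T_o,
        C_orth=pd.DataFrame(C_o, index=Yf.columns),
        Q_orth=pd.DataFrame(Q_o, index=Yf.columns),
        U_orth=U_o,
        B_t=B_t, B_u=B_u,
        x_mean=x_mean, y_mean=y_mean, x_scale=x_sd, y_scale=y_sd,
        n_joint=n_joint, n_orth_x=n_orth_x, n_orth_y=n_orth_y,
        metadata={
            "preprocessing": "center+unit_variance" if scale else "center",
            "algorithm": "cross-covariance SVD with orthogonal deflation",
            "sign_convention": "largest-|loading| element positive",
            "orth_cross_joint_cov": cross_joint_cov,
        },
    )
    return model


def top_joint_loadings(model: O2plsModel, k: int = 25
                       ) -> dict[str, pd.DataFrame]:
    """Top-k features per block ranked by max |joint loading|.

    Returns ``{"genes": ..., "proteins": ...}`` DataFrames with columns
    feature, loading (signed value on the maximizing component) and
    abs_loading, sorted descending with lexicographic tie-break. ``k``
    larger than the block returns the full ranking. Features whose joint
    loading is exactly zero carry no shared signal and are excluded (they
    would otherwise fill trailing slots purely by id order on degenerate,
    e.g. noise-free, inputs).
    """
    if k < 1:
        raise DomainError("k must be >= 1")
    out = {}
    for key, L in (("genes", model.W), ("proteins", model.C)):
        absmax = L.abs().max(axis=1)
        which = L.abs().to_numpy().argmax(axis=1)
        signed = L.to_numpy()[np.arange(len(L)), which]
        df = pd.DataFrame({"feature": L.index.astype(str),
                           "loading": signed,
                           "abs_loading": absmax.to_numpy()})
        # numerically-zero loadings (relative to the block's largest) carry
        # no joint signal and would fill trailing slots purely by id order
        df = df[df["abs_loading"] > 1e-12 * df["abs_loading"].max()]
        df = df.sort_values(["abs_loading", "feature"],
                            ascending=[False, True], kind="stable")
        out[key] = df.head(k).reset_index(drop=True)
    return out


def variance_explained(model: O2plsModel, X, Y) -> pd.DataFrame:
    """R-squared partition (joint / orthogonal / residual) per block.

    Sums of squares are measured against the centered (and, if the model
    was fit with scaling, scaled) blocks; for a valid fit the three parts
    sum to 1 per block up to numerical tolerance.
    """
    Xf = _as_frame(X, "x")
    Yf = _as_frame(Y, "y")
    rows = []
    for name, F, mean, sd, S, L, S_o, P_o in (
        ("genes", Xf, model.x_mean, model.x_scale, model.T, model.W,
         model.T_orth, model.P_orth),
        ("proteins", Yf, model.y_mean, model.y_scale, model.U, model.C,
         model.U_orth, model.Q_orth),
    ):
        Z = (F - mean)
        if sd is not None:
            Z = Z / sd
        Z = Z.to_numpy()
        ss_total = float((Z**2).sum())
        if ss_total == 0:
            raise DomainError(f"{name} block has no variance")
        joint = S @ L.to_numpy().T
        orth = S_o @ P_o.to_numpy().T if S_o.shape[1] else np.zeros_like(Z)
        resid = Z - joint - orth
        rows.append((name,
                     float((joint**2).sum()) / ss_total,
                     float((orth**2).sum()) / ss_total,
                     float((resid**2).sum()) / ss_total))
    return pd.DataFrame(rows, columns=["block", "r2_joint", "r2_orth",
                                       "r2_residual"]).set_index("block")
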