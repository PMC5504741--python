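"""Regularized canonical correlation analysis for paired omics layers.

Classic CCA fails when variables outnumber samples; ridge regularization
of the within-layer covariance matrices (Cxx + lambda*I) restores
well-posedness.  The per-layer ridge weights are estimated analytically as
the shrinkage intensity of the empirical correlation matrix toward the
identity target: lambda* = sum of estimated variances of the off-diagonal
correlations divided by the sum of their squares, clipped to [0, 1].
Variables are standardized internally so covariance and correlation
formulations coincide and lambda is interpretable as a correlation
shrinkage weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats as sps

from .matrix import OmicsMatrix
from .stats import adjust_fdr


def pair_samples(x: OmicsMatrix, y: OmicsMatrix) -> tuple[OmicsMatrix, OmicsMatrix]:
    """Restrict both layers to their shared samples, in x's order."""
    shared = set(x.sample_ids) & set(y.sample_ids)
    if not shared:
        raise ValueError("no shared samples between layers")
    order = [s for s in x.sample_ids if s in shared]
    return x.subset_samples(order), y.subset_samples(order)


def select_top_variance(m: OmicsMatrix, k: int) -> OmicsMatrix:
    """Keep the k variables with the largest sample variance.

    Ties are broken by variable id (lexicographic) for determinism.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > m.n_variables:
        raise ValueError(f"k={k} exceeds {m.n_variables} variables")
    var = m.values.var(axis=1, ddof=1)
    order = sorted(range(m.n_variables), key=lambda i: (-var[i], m.variable_ids[i]))
    ids = sorted(m.variable_ids[i] for i in order[:k])
    return m.subset_variables(ids)


def estimate_shrinkage_lambda(data: np.ndarray) -> float:
    """Analytic shrinkage intensity toward the identity correlation target.

    ``data`` is samples x variables.  Off-diagonal entries r_ij of the
    empirical correlation matrix get
    lambda* = sum var-hat(r_ij) / sum r_ij^2, clipped to [0, 1], with
    var-hat(r_ij) = n / (n-1)^3 * sum_k (w_kij - mean w_ij)^2 over products
    w_kij of standardized observations.
    """
    X = np.asarray(data, dtype=float)
    n, p = X.shape
    if n < 3:
        raise ValueError("need at least 3 samples")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = int(np.argmax(sd == 0))
        raise ValueError(f"zero-variance variable at column {bad}; remove first")
    Z = (X - X.mean(axis=0)) / sd
    R = Z.T @ Z / (n - 1)
    # var-hat of each r_ij from the empirical variance of the w products
    W_mean = R * (n - 1) / n
    sum_w_sq = (Z ** 2).T @ (Z ** 2)          # sum_k w_kij^2
    var_w = (sum_w_sq - n * W_mean ** 2)
    var_r = n / (n - 1.0) ** 3 * var_w
    off = ~np.eye(p, dtype=bool)
    denom = float((R[off] ** 2).sum())
    if denom == 0:
        return 1.0
    lam = float(var_r[off].sum() / denom)
    return min(max(lam, 0.0), 1.0)


@dataclass
class CCAModel:
    """Fitted regularized-CCA decomposition of two paired layers."""

    canonical_correlations: np.ndarray      # non-increasing, in [0, 1]
    x_weights: pd.DataFrame                 # variables x components
    y_weights: pd.DataFrame
    x_scores: pd.DataFrame                  # samples x components
    y_scores: pd.DataFrame
    lambda_x: float
    lambda_y: float
    x_variables: list[str] = field(default_factory=list)
    y_variables: list[str] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return len(self.canonical_correlations)


def _standardize(values: np.ndarray) -> np.ndarray:
    sd = values.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("zero-variance variable; remove before CCA")
    return (values - values.mean(axis=0)) / sd


def fit_rcca(
    x: OmicsMatrix,
    y: OmicsMatrix,
    lambda_x: float | None = None,
    lambda_y: float | None = None,
    n_components: int = 2,
    standardize: bool = True,
) -> CCAModel:
    """Fit ridge-regularized CCA on two sample-paired matrices.

    The weights are the leading solutions of the generalized eigenproblem
    (Cxx + lx*I)^-1 Cxy (Cyy + ly*I)^-1 Cyx a = rho^2 a, solved through the
    SVD of the doubly-whitened cross-covariance.  When a lambda is None it
    is estimated by the analytic shrinkage formula.  Component signs are
    fixed so that each component's largest-magnitude x-weight is positive.
    """
    if x.sample_ids != y.sample_ids:
        raise ValueError("layers are not sample-paired; run pair_samples first")
    Xs = x.values.T.astype(float)           # samples x p
    Ys = y.values.T.astype(float)
    if standardize:
        Xs, Ys = _standardize(Xs), _standardize(Ys)
    else:
        Xs = Xs - Xs.mean(axis=0)
        Ys = Ys - Ys.mean(axis=0)
    n, p = Xs.shape
    q = Ys.shape[1]
    if lambda_x is None:
        lambda_x = estimate_shrinkage_lambda(Xs)
    if lambda_y is None:
        lambda_y = estimate_shrinkage_lambda(Ys)
    if not (0 <= lambda_x <= 1 and 0 <= lambda_y <= 1):
        raise ValueError("regularization weights must lie in [0, 1]")

    Cxx = Xs.T @ Xs / (n - 1) + lambda_x * np.eye(p)
    Cyy = Ys.T @ Ys / (n - 1) + lambda_y * np.eye(q)
    Cxy = Xs.T @ Ys / (n - 1)

    # inverse symmetric square roots of the regularized covariances
    def inv_sqrt(C: np.ndarray) -> np.ndarray:
        w, V = linalg.eigh(C)
        if w.min() <= 1e-12:
            raise ValueError(
                "regularized covariance numerically singular; increase lambda"
            )
        return V @ np.diag(1.0 / np.sqrt(w)) @ V.T

    Wx, Wy = inv_sqrt(Cxx), inv_sqrt(Cyy)
    K = Wx @ Cxy @ Wy
    U, s, Vt = np.linalg.svd(K)
    max_rank = int((s > 1e-12).sum())
    if n_components > min(p, q):
        raise ValueError(
            f"n_components={n_components} exceeds min(p, q)={min(p, q)}"
        )
    if n_components > max_rank:
        raise ValueError(
            f"n_components={n_components} exceeds numerical rank {max_rank}"
        )
    rho = np.clip(s[:n_components], 0.0, 1.0)
    A = Wx @ U[:, :n_components]            # x weights
    B = Wy @ Vt[:n_components].T            # y weights
    # deterministic sign: largest-|weight| x-entry positive per component
    for k in range(n_components):
        j = int(np.argmax(np.abs(A[:, k])))
        if A[j, k] < 0:
            A[:, k] *= -1.0
            B[:, k] *= -1.0
    comp = [f"CC{k + 1}" for k in range(n_components)]
    return CCAModel(
        canonical_correlations=rho,
        x_weights=pd.DataFrame(A, index=x.variable_ids, columns=comp),
        y_weights=pd.DataFrame(B, index=y.variable_ids, columns=comp),
        x_scores=pd.DataFrame(Xs @ A, index=x.sample_ids, columns=comp),
        y_scores=pd.DataFrame(Ys @ B, index=y.sample_ids, columns=comp),
        lambda_x=float(lambda_x),
        lambda_y=float(lambda_y),
        x_variables=list(x.variable_ids),
        y_variables=list(y.variable_ids),
    )


def variate_variable_correlations(
    model: CCAModel, x: OmicsMatrix, y: OmicsMatrix
) -> pd.DataFrame:
    """Correlate every original variable with each layer's canonical scores.

    Long-format output with Pearson r, the t-transform p-value and BH
    adjustment within each component x layer family.  Constant variables
    are reported with a ``constant`` flag and missing statistics.
    """
    n = len(model.x_scores)
    frames = []
    for layer_name, m, scores in (
        ("x", x, model.x_scores),
        ("y", y, model.y_scores),
    ):
        vals = m.values  # variables x samples
        sd = vals.std(axis=1, ddof=1)
        centered = vals - vals.mean(axis=1, keepdims=True)
        for comp in scores.columns:
            s = scores[comp].to_numpy()
            s_c = s - s.mean()
            with np.errstate(invalid="ignore", divide="ignore"):
                r = (centered @ s_c) / (
                    np.sqrt((centered ** 2).sum(axis=1)) * np.sqrt((s_c ** 2).sum())
                )
            constant = sd == 0
            r = np.where(constant, np.nan, np.clip(r, -1.0, 1.0))
            with np.errstate(invalid="ignore", divide="ignore"):
                t = r * np.sqrt((n - 2) / np.maximum(1.0 - r ** 2, 1e-300))
            p = 2.0 * sps.t.sf(np.abs(t), df=n - 2)
            ok = ~constant
            p_adj = np.full_like(p, np.nan)
            if ok.any():
                p_adj[ok] = adjust_fdr(p[ok])
            frames.append(pd.DataFrame({
                "variable_id": m.variable_ids,
                "layer": layer_name,
                "component": comp,
                "r": r,
                "p_value": np.where(constant, np.nan, p),
                "p_adjusted": p_adj,
                "constant": constant,
            }))
    return pd.concat(frames, ignore_index=True)
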