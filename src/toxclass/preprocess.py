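"""From normalized expression to analysis-ready contrasts.

The pipeline's working representation is the contrast matrix: each treated
sample minus the mean of its matched untreated controls from the same
experiment (paired design). This simple subtraction removes most of the
batch structure, and downstream stages operate on it directly. A
location/scale empirical-Bayes batch adjustment (the ComBat model) is also
provided for the comparison view on absolute expression; PCA, variance
ranking and hierarchical clustering support the exploratory figures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage

from .datatypes import (
    CONTROL,
    ContrastMatrix,
    ExpressionMatrix,
    PairingError,
    SampleMetadata,
    ValidationError,
)


def subtract_controls(expr: ExpressionMatrix, meta: SampleMetadata) -> ContrastMatrix:
    """Per treated sample, subtract the mean of its matched controls.

    Output columns are exactly the treated samples, in metadata order;
    control columns are dropped. When a sample has two matched controls
    their mean is formed before subtraction.
    """
    df = expr.data
    cols = {}
    for sid in meta.treated_ids:
        ctrls = meta.controls_of(sid)
        if not ctrls:
            raise PairingError(f"treated sample {sid!r} has no matched control")
        missing = [c for c in [sid, *ctrls] if c not in df.columns]
        if missing:
            raise ValidationError(f"samples missing from expression matrix: {missing}")
        cols[sid] = df[sid] - df[list(ctrls)].mean(axis=1)
    return ContrastMatrix(pd.DataFrame(cols, index=df.index))


@dataclass
class BatchModel:
    """Fitted location/scale batch parameters and their EB-shrunken versions.

    gamma_hat / delta2_hat are the per-(batch, probe) location and scale
    estimates on standardized data; gamma_star / delta2_star are the
    empirical-Bayes estimates under a normal location prior and an
    inverse-gamma scale prior (method-of-moments hyperparameters).
    """

    batches: list
    gamma_hat: pd.DataFrame  # probe x batch
    delta2_hat: pd.DataFrame
    gamma_star: pd.DataFrame
    delta2_star: pd.DataFrame
    gamma_bar: pd.Series  # per-batch prior mean of gamma
    tau2_bar: pd.Series  # per-batch prior variance of gamma
    a_prior: pd.Series  # per-batch inverse-gamma shape
    b_prior: pd.Series  # per-batch inverse-gamma scale


def _ig_moments(delta2: np.ndarray) -> tuple[float, float]:
    """Method-of-moments inverse-gamma hyperparameters from scale estimates."""
    m = delta2.mean()
    v = delta2.var(ddof=1)
    a = (2.0 * v + m**2) / v
    b = (m * v + m**3) / v
    return float(a), float(b)


def combat_adjust(
    expr: ExpressionMatrix,
    meta: SampleMetadata,
    parametric: bool = True,
    covariate_treatment: bool = True,
    tol: float = 1e-4,
    max_iter: int = 200,
) -> tuple[ExpressionMatrix, BatchModel]:
    """Location/scale empirical-Bayes batch adjustment (the ComBat model).

    Per probe, the data are standardized by a linear model with batch
    indicators (and, by default, a treated/control covariate so treatment
    signal is not absorbed into the batch terms); per-batch location and
    scale are estimated on the standardized residual scale, shrunk toward
    a normal / inverse-gamma prior by iterated conditional updates, and
    removed. With ``parametric=False`` the raw per-batch estimates are used
    without shrinkage (a direct per-batch standardization).
    """
    batch = meta.batch_ids.reindex(expr.sample_ids)
    if batch.isna().any():
        raise ValidationError("expression contains samples absent from metadata")
    batches = list(dict.fromkeys(batch))
    if len(batches) < 2:
        raise ValidationError("combat_adjust requires >= 2 batches")
    counts = batch.value_counts()
    small = [b for b in batches if counts[b] < 2]
    if small:
        raise ValidationError(f"batches with a single sample: {small}")

    Y = expr.values  # G x n
    G, n = Y.shape
    # Design: per-batch intercepts (+ treatment covariate).
    X_parts = [np.asarray([1.0 * (b == bb) for b in batch]) for bb in batches]
    treated = set(meta.treated_ids)
    if covariate_treatment:
        X_parts.append(np.asarray([1.0 * (s in treated) for s in expr.sample_ids]))
    X = np.column_stack(X_parts)  # n x p
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)  # p x G
    n_per_batch = np.array([counts[b] for b in batches], dtype=float)
    # Grand mean = batch-size-weighted mean of batch intercepts (+ covariates).
    grand = (n_per_batch / n) @ beta[: len(batches)]  # G
    fitted_cov = (
        X[:, len(batches):] @ beta[len(batches):] if covariate_treatment else 0.0
    )  # n x G
    stand_mean = grand[None, :] + fitted_cov  # n x G
    resid = Y.T - X @ beta  # n x G
    pooled_var = (resid**2).sum(axis=0) / n  # G
    pooled_var = np.maximum(pooled_var, 1e-12)
    sd = np.sqrt(pooled_var)
    Z = (Y.T - stand_mean) / sd[None, :]  # n x G standardized

    gamma_hat = np.empty((G, len(batches)))
    delta2_hat = np.empty((G, len(batches)))
    for bi, bb in enumerate(batches):
        mask = (batch == bb).to_numpy()
        Zb = Z[mask]
        gamma_hat[:, bi] = Zb.mean(axis=0)
        delta2_hat[:, bi] = Zb.var(axis=0, ddof=1)
    delta2_hat = np.maximum(delta2_hat, 1e-12)

    gamma_bar = gamma_hat.mean(axis=0)
    tau2_bar = gamma_hat.var(axis=0, ddof=1)
    a_prior = np.empty(len(batches))
    b_prior = np.empty(len(batches))
    for bi in range(len(batches)):
        a_prior[bi], b_prior[bi] = _ig_moments(delta2_hat[:, bi])

    if parametric:
        gamma_star = gamma_hat.copy()
        delta2_star = delta2_hat.copy()
        for bi, bb in enumerate(batches):
            mask = (batch == bb).to_numpy()
            Zb = Z[mask]
            nb = mask.sum()
            g_new = gamma_hat[:, bi]
            d_new = delta2_hat[:, bi]
            for _ in range(max_iter):
                g_old, d_old = g_new, d_new
                g_new = (nb * tau2_bar[bi] * gamma_hat[:, bi] + d_old * gamma_bar[bi]) / (
                    nb * tau2_bar[bi] + d_old
                )
                ss = ((Zb - g_new[None, :]) ** 2).sum(axis=0)
                d_new = (b_prior[bi] + 0.5 * ss) / (nb / 2.0 + a_prior[bi] - 1.0)
                change = max(
                    np.abs(g_new - g_old).max() / max(np.abs(g_old).max(), 1e-12),
                    np.abs(d_new - d_old).max() / d_old.max(),
                )
                if change < tol:
                    break
            gamma_star[:, bi] = g_new
            delta2_star[:, bi] = d_new
    else:
        gamma_star = gamma_hat.copy()
        delta2_star = delta2_hat.copy()

    adjusted = np.empty_like(Z)
    for bi, bb in enumerate(batches):
        mask = (batch == bb).to_numpy()
        adjusted[mask] = (Z[mask] - gamma_star[:, bi][None, :]) / np.sqrt(
            delta2_star[:, bi]
        )[None, :]
    out = adjusted * sd[None, :] + stand_mean  # n x G
    adj_expr = ExpressionMatrix(
        pd.DataFrame(out.T, index=expr.probe_ids, columns=expr.sample_ids)
    )
    pidx = expr.probe_ids
    model = BatchModel(
        batches=batches,
        gamma_hat=pd.DataFrame(gamma_hat, index=pidx, columns=batches),
        delta2_hat=pd.DataFrame(delta2_hat, index=pidx, columns=batches),
        gamma_star=pd.DataFrame(gamma_star, index=pidx, columns=batches),
        delta2_star=pd.DataFrame(delta2_star, index=pidx, columns=batches),
        gamma_bar=pd.Series(gamma_bar, index=batches),
        tau2_bar=pd.Series(tau2_bar, index=batches),
        a_prior=pd.Series(a_prior, index=batches),
        b_prior=pd.Series(b_prior, index=batches),
    )
    return adj_expr, model


@dataclass
class PCAResult:
    """Sample-space principal components of a probe x sample matrix."""

    scores: pd.DataFrame  # sample x component
    loadings: pd.DataFrame  # probe x component
    explained_variance_ratio: np.ndarray


def pca(data, n_components: int = 2) -> PCAResult:
    """Column-centred SVD PCA of the samples.

    Signs are fixed by making the largest-magnitude loading of each
    component positive, so results are deterministic.
    """
    X = data.values.T  # samples x probes
    n, p = X.shape
    if n < 2:
        raise ValidationError("pca requires >= 2 samples")
    if n_components > min(n, p):
        raise ValidationError(
            f"n_components={n_components} exceeds min(dims)={min(n, p)}"
        )
    Xc = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    comps = range(n_components)
    scores = U[:, :n_components] * S[:n_components]
    loadings = Vt[:n_components].T
    for j in comps:
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    total_var = (S**2).sum()
    evr = (S[:n_components] ** 2) / total_var if total_var > 0 else np.zeros(n_components)
    names = [f"PC{j + 1}" for j in comps]
    return PCAResult(
        scores=pd.DataFrame(scores, index=data.sample_ids, columns=names),
        loadings=pd.DataFrame(loadings, index=data.probe_ids, columns=names),
        explained_variance_ratio=evr,
    )


def top_variance_features(data, n: int) -> pd.Series:
    """The n probes with highest (n-1)-denominator sample variance.

    Returns a Series (probe -> variance) sorted by descending variance,
    ties broken lexicographically by probe id.
    """
    if n > data.shape[0]:
        raise ValidationError(f"n={n} exceeds number of probes {data.shape[0]}")
    var = data.data.var(axis=1, ddof=1)
    order = sorted(var.index, key=lambda p: (-var[p], str(p)))
    return var.loc[order[:n]]


@dataclass
class Dendrogram:
    """Agglomerative clustering result over matrix columns (samples).

    ``merges`` lists (left, right, height, size) in merge order where left
    and right index either original items (< n) or earlier merges (>= n),
    matching the scipy linkage convention. ``linkage_matrix`` is the raw
    scipy array for plotting.
    """

    items: list
    merges: list[tuple[int, int, float, int]]
    linkage_matrix: np.ndarray

    def cut(self, n_clusters: int) -> dict:
        """Item -> cluster id for a flat cut into n_clusters groups."""
        from scipy.cluster.hierarchy import fcluster

        labels = fcluster(self.linkage_matrix, n_clusters, criterion="maxclust")
        return dict(zip(self.items, labels))


def hierarchical_cluster(data, method: str = "complete") -> Dendrogram:
    """Euclidean agglomerative clustering of the samples (columns)."""
    if method not in ("complete", "average"):
        raise ValidationError(f"unsupported linkage {method!r}")
    X = data.values.T
    if X.shape[0] < 2:
        raise ValidationError("need >= 2 items to cluster")
    if not np.isfinite(X).all():
        raise ValidationError("non-finite values in clustering input")
    Z = linkage(X, method=method, metric="euclidean")
    merges = [
        (int(a), int(b), float(h), int(s)) for a, b, h, s in Z
    ]
    return Dendrogram(items=list(data.sample_ids), merges=merges, linkage_matrix=Z)
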