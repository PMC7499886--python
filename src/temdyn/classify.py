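"""Bipartite TE classification from temporal 24-nt siRNA profiles.

TEs are clustered on their replicate-mean RPM profiles with a Gaussian
mixture constrained to the VEV covariance family,

    Sigma_k = lambda_k * D_k * A * D_k^T,

variable volume lambda_k > 0, a shape matrix A (diagonal, det 1) shared
by all components, and variable orthogonal orientation D_k. Component
count is selected by BIC (2*loglik - m*log n, larger better) over a grid
of even G, taking the smallest G at the maximum. Clusters are then
merged into the bipartite classes by correlating each cluster's mean
temporal profile with two fixed stage templates: class A peaks at
maturity and post-embryonically, class B peaks mid-embryogenesis and
collapses at maturity. TEs never reaching the detection threshold
(2 RPM, max across samples of the replicate-mean) are called depleted.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.special import logsumexp
from sklearn.cluster import kmeans_plusplus

from .config import DETECTION_RPM, LENGTH_MEDIUM_MAX, LENGTH_SHORT_MAX

logger = logging.getLogger(__name__)


class FitError(RuntimeError):
    """Raised when a mixture model cannot be fitted."""


def n_free_params(G: int, d: int) -> int:
    """Free-parameter count of a VEV mixture in d dimensions:
    proportions + means + volumes + shared shape + orientations."""
    return (G - 1) + G * d + G + (d - 1) + G * d * (d - 1) // 2


@dataclass
class GmmModel:
    """A fitted VEV Gaussian mixture."""

    G: int
    weights: np.ndarray            # pi_k
    means: np.ndarray              # (G, d)
    volumes: np.ndarray            # lambda_k
    shape: np.ndarray              # diag of A, det 1
    orientations: np.ndarray       # (G, d, d), D_k orthogonal
    loglik: float
    loglik_trace: list[float]
    bic: float
    responsibilities: np.ndarray   # (n, G)
    bic_table: pd.Series | None = None

    @property
    def covariances(self) -> np.ndarray:
        return np.stack([
            lam * D @ np.diag(self.shape) @ D.T
            for lam, D in zip(self.volumes, self.orientations)
        ])

    @property
    def labels(self) -> np.ndarray:
        return self.responsibilities.argmax(axis=1)


def _log_gaussian(X: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    d = X.shape[1]
    L = np.linalg.cholesky(cov)
    diff = X - mean
    sol = np.linalg.solve(L, diff.T)
    logdet = 2.0 * np.log(np.diag(L)).sum()
    return -0.5 * (d * np.log(2 * np.pi) + logdet + (sol ** 2).sum(axis=0))


def _vev_mstep(W: np.ndarray, nk: np.ndarray, floor: float, inner_iter: int = 20):
    """Closed-ish M-step for the VEV family (alternating A and lambda).

    ``W``: per-component scatter matrices. Orientations are eigenvectors
    of W_k; the shared shape A and per-component volumes are obtained by
    alternating minimization, eigenvalues floored for stability.
    """
    G, d, _ = W.shape
    omegas = np.empty((G, d))
    D = np.empty((G, d, d))
    for k in range(G):
        vals, vecs = np.linalg.eigh(W[k])
        order = np.argsort(vals)[::-1]          # descending, matching sorted A
        omegas[k] = np.maximum(vals[order], floor * max(nk[k], 1.0))
        D[k] = vecs[:, order]
    lam = np.exp(np.mean(np.log(omegas), axis=1)) / np.maximum(nk, 1.0)
    lam = np.maximum(lam, floor)
    A = np.ones(d)
    for _ in range(inner_iter):
        A_new = (omegas / lam[:, None]).sum(axis=0)
        A_new = np.maximum(A_new, 1e-12)
        A_new = A_new / np.exp(np.mean(np.log(A_new)))  # det 1
        lam_new = (omegas / A_new[None, :]).mean(axis=1) / np.maximum(nk, 1.0)
        lam_new = np.maximum(lam_new, floor)
        if np.allclose(A_new, A, rtol=1e-10) and np.allclose(lam_new, lam, rtol=1e-10):
            A, lam = A_new, lam_new
            break
        A, lam = A_new, lam_new
    return lam, A, D


def fit_gmm_vev(
    X: np.ndarray | pd.DataFrame,
    G: int,
    seed: int = 0,
    n_init: int = 10,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> GmmModel:
    """EM for a VEV-constrained Gaussian mixture, best of ``n_init``
    k-means++ initializations. The log-likelihood trace is recorded and
    non-decreasing up to the numerical floor."""
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    if G < 1:
        raise FitError("G must be >= 1")
    if n <= G:
        raise FitError(f"need more rows ({n}) than components ({G})")
    floor = 1e-8 * max(float(np.var(X)), 1e-12)
    rng = np.random.default_rng(seed)

    best: GmmModel | None = None
    for init in range(n_init):
        model = _fit_once(X, G, rng, max_iter, tol, floor)
        if model is not None and (best is None or model.loglik > best.loglik):
            best = model
    if best is None:
        raise FitError(f"all {n_init} EM initializations failed for G={G}")
    m = n_free_params(G, d)
    best.bic = 2.0 * best.loglik - m * np.log(n)
    return best


def _fit_once(X, G, rng, max_iter, tol, floor) -> GmmModel | None:
    n, d = X.shape
    centers, _ = kmeans_plusplus(X, n_clusters=G,
                                 random_state=int(rng.integers(2 ** 31)))
    means = centers.astype(float)
    base_cov = np.cov(X.T) + floor * np.eye(d)
    if d == 1:
        base_cov = base_cov.reshape(1, 1)
    lam = np.ones(G)
    A = np.ones(d)
    D = np.stack([np.linalg.eigh(base_cov)[1][:, ::-1]] * G)
    # start from the pooled covariance for every component
    covs = np.stack([base_cov] * G)
    weights = np.full(G, 1.0 / G)

    loglik_trace: list[float] = []
    prev = -np.inf
    resp = np.zeros((n, G))
    for it in range(max_iter):
        # E-step
        log_p = np.empty((n, G))
        try:
            for k in range(G):
                log_p[:, k] = np.log(weights[k] + 1e-300) + _log_gaussian(X, means[k], covs[k])
        except np.linalg.LinAlgError:
            return None
        norm = logsumexp(log_p, axis=1)
        loglik = float(norm.sum())
        resp = np.exp(log_p - norm[:, None])
        loglik_trace.append(loglik)
        if abs(loglik - prev) < tol * (1 + abs(loglik)):
            prev = loglik
            break
        prev = loglik
        # M-step
        nk = resp.sum(axis=0)
        for k in np.flatnonzero(nk < 1e-6):
            # dead component: reseed at a random point, keep EM going
            logger.debug("reseeding starving component %d", k)
            j = int(rng.integers(n))
            resp[:, k] = 0.0
            resp[j, :] = 0.0
            resp[j, k] = 1.0
            nk = resp.sum(axis=0)
        weights = nk / n
        means = (resp.T @ X) / np.maximum(nk, 1e-12)[:, None]
        W = np.empty((G, d, d))
        for k in range(G):
            diff = X - means[k]
            W[k] = (resp[:, k][:, None] * diff).T @ diff
        lam, A, D = _vev_mstep(W, nk, floor)
        covs = np.stack([lam[k] * D[k] @ np.diag(A) @ D[k].T for k in range(G)])
        covs += floor * np.eye(d)
    return GmmModel(
        G=G, weights=weights, means=means, volumes=lam, shape=A,
        orientations=D, loglik=prev, loglik_trace=loglik_trace,
        bic=np.nan, responsibilities=resp,
    )


def select_model_bic(
    X: np.ndarray | pd.DataFrame,
    G_grid=tuple(range(2, 21, 2)),
    seed: int = 0,
) -> GmmModel:
    """Fit each G on the grid; return the model at the smallest G that
    achieves the maximum BIC. The full BIC table is retained on the
    returned model (``bic_table``); failed fits are recorded as NaN."""
    models: dict[int, GmmModel] = {}
    table = {}
    errors = {}
    for G in G_grid:
        try:
            m = fit_gmm_vev(X, G, seed=seed + G)
            models[G] = m
            table[G] = m.bic
        except (FitError, np.linalg.LinAlgError) as exc:
            table[G] = np.nan
            errors[G] = str(exc)
            logger.warning("GMM fit failed for G=%d: %s", G, exc)
    bic_table = pd.Series(table, name="bic")
    if not models:
        raise FitError(f"all fits failed: {errors}")
    finite = bic_table.dropna()
    best_bic = finite.max()
    best_G = int(min(g for g, b in finite.items() if b == best_bic))
    best = models[best_G]
    best.bic_table = bic_table
    return best


# ---------------------------------------------------------------------------
# class assignment
# ---------------------------------------------------------------------------

def assign_bipartite_classes(
    clusters: np.ndarray,
    X: pd.DataFrame,
    threshold_rpm: float = DETECTION_RPM,
    templates: dict[str, dict[str, float]] | None = None,
) -> pd.DataFrame:
    """Label every TE as class A, B, depleted, or unclassified.

    TEs whose max replicate-mean RPM across samples is below
    ``threshold_rpm`` are depleted. Remaining clusters inherit the label
    of whichever stage template (A: late/post-embryonic peak; B:
    mid-embryogenesis peak) their mean profile correlates with more;
    a cluster equally correlated with both (|delta r| < 1e-6) is
    reported as unclassified, never silently assigned.
    """
    from .synthetic import STAGE_TEMPLATES

    if templates is None:
        templates = {k: STAGE_TEMPLATES[k] for k in ("A", "B")}
    clusters = np.asarray(clusters)
    if len(clusters) != len(X):
        raise ValueError("cluster vector and expression matrix disagree in length")
    stages = list(X.columns)
    tvec = {k: np.array([templates[k][s] for s in stages]) for k in templates}

    labels = pd.Series(index=X.index, dtype=object)
    cluster_label: dict[int, str] = {}
    for c in np.unique(clusters):
        profile = X.loc[clusters == c].mean(axis=0).to_numpy()
        rs = {}
        for k, tv in tvec.items():
            sd_p, sd_t = profile.std(), tv.std()
            rs[k] = (
                float(np.corrcoef(profile, tv)[0, 1]) if sd_p > 0 and sd_t > 0 else 0.0
            )
        ra, rb = rs.get("A", 0.0), rs.get("B", 0.0)
        if abs(ra - rb) < 1e-6:
            cluster_label[c] = "unclassified"
            logger.warning("cluster %s equally correlated with both templates", c)
        else:
            cluster_label[c] = "A" if ra > rb else "B"
    for c, lbl in cluster_label.items():
        labels[clusters == c] = lbl

    detected = X.max(axis=1) >= threshold_rpm
    labels[~detected] = "depleted"
    return pd.DataFrame({"te_id": X.index, "cluster": clusters,
                         "te_class": labels.to_numpy()}).set_index("te_id")


# ---------------------------------------------------------------------------
# ordination / clustering / partitions
# ---------------------------------------------------------------------------

@dataclass
class PcaResult:
    loadings: np.ndarray            # (d, d) columns = principal axes
    scores: np.ndarray              # (n, d)
    variance_explained: np.ndarray  # sums to 1 unless degenerate
    degenerate: bool = False


def pca(X: np.ndarray | pd.DataFrame) -> PcaResult:
    """Principal components of column-centered (never scaled) data."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("pca needs at least 2 rows and 2 columns")
    centered = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(centered, full_matrices=False)
    var = s ** 2
    total = var.sum()
    if total == 0:
        return PcaResult(loadings=Vt.T, scores=U * s,
                         variance_explained=np.zeros_like(var), degenerate=True)
    return PcaResult(loadings=Vt.T, scores=U * s, variance_explained=var / total)


def hierarchical_cluster(X: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Complete-linkage agglomeration on Euclidean distances between rows.

    Returns the scipy linkage matrix; merge heights are non-decreasing.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 observations")
    return linkage(X, method="complete", metric="euclidean")


def length_partition(annotation_or_lengths) -> pd.Series:
    """Short (<= 723 bp), medium (724-2114 bp), long (> 2114 bp) labels."""
    if isinstance(annotation_or_lengths, pd.DataFrame):
        lengths = pd.Series(
            (annotation_or_lengths["end"] - annotation_or_lengths["start"]).to_numpy(),
            index=pd.Index(annotation_or_lengths["te_id"], name="te_id"),
        )
    else:
        lengths = pd.Series(annotation_or_lengths)
    if (lengths < 1).any():
        raise ValueError("TE lengths must be >= 1")
    out = pd.Series("medium", index=lengths.index, dtype=object)
    out[lengths <= LENGTH_SHORT_MAX] = "short"
    out[lengths > LENGTH_MEDIUM_MAX] = "long"
    return out
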