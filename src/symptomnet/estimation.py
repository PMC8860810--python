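"""Regularized partial-correlation network estimation.

The estimator is the standard Gaussian graphical model chain used in
network psychometrics: sample correlation matrix -> graphical lasso over
a decreasing log-spaced penalty grid -> extended BIC (EBIC) model
selection -> partial-correlation edge weights.  For penalty lambda the
graphical lasso maximizes

    log det K - trace(S K) - lambda * sum_{i != j} |K_ij|

over positive-definite precision matrices K; the edge weight between
nodes i and j is the partial correlation -K_ij / sqrt(K_ii K_jj).  The
EBIC of a fitted model with E edges is

    -2 L + E log n + 4 E gamma log p,

with L = (n/2)(log det K - trace(S K)); gamma = 0.5 (the hyperprior used
throughout this package by default) favors sparser graphs than plain BIC.

The per-lambda solve is delegated to scikit-learn's coordinate-descent
graphical lasso, warm-started along the path; grid construction, EBIC
scoring and selection are implemented here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.exceptions import ConvergenceWarning

from .datasets import SubscaleDataset

try:  # warm-startable path solver (public API exposes no cov_init)
    from sklearn.covariance._graph_lasso import _graphical_lasso

    def _solve_glasso(S, lam, cov_init, max_iter, mode="cd"):
        cov, prec, *_ = _graphical_lasso(
            S, lam, cov_init=cov_init, mode=mode, max_iter=max_iter, tol=1e-4
        )
        return cov, prec

except ImportError:  # pragma: no cover - exercised only on other sklearn builds
    from sklearn.covariance import graphical_lasso as _public_glasso

    def _solve_glasso(S, lam, cov_init, max_iter, mode="cd"):
        return _public_glasso(S, alpha=lam, mode=mode, max_iter=max_iter, tol=1e-4)


EDGE_TOL = 1e-8  # |weight| above which an edge counts as present
GAP_TOL = 1e-2  # dual-gap magnitude accepted when the solver stalls


class EstimationError(ValueError):
    """Raised for invalid estimation inputs."""


class GlassoConvergenceError(RuntimeError):
    """The graphical-lasso solver failed to converge at some penalty."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class CorrelationMatrix:
    """Sample correlation matrix plus provenance."""

    S: np.ndarray
    method: str
    n: int
    repaired: bool = False  # True if eigenvalue clipping was applied

    @property
    def p(self) -> int:
        return self.S.shape[0]


@dataclass
class LambdaPath:
    """Decreasing positive penalty grid; first element is lambda_max."""

    lambdas: np.ndarray

    @property
    def n_lambda(self) -> int:
        return len(self.lambdas)


@dataclass
class PathFit:
    """Per-penalty glasso solutions and their EBIC ingredients."""

    lambdas: np.ndarray
    precisions: list[np.ndarray]
    pcors: list[np.ndarray]
    edge_counts: np.ndarray
    logliks: np.ndarray
    n: int
    p: int

    def ebics(self, gamma: float) -> np.ndarray:
        return np.array(
            [
                ebic(L, E, self.n, self.p, gamma)
                for L, E in zip(self.logliks, self.edge_counts)
            ]
        )


@dataclass
class RegularizedNetwork:
    """Selected partial-correlation network.

    ``W`` is the symmetric edge-weight matrix (selected partial
    correlations, zero diagonal).
    """

    node_names: list[str]
    W: np.ndarray
    lambda_selected: float
    gamma: float
    n: int
    group_label: str = ""
    metadata: dict = field(default_factory=dict)

    @property
    def p(self) -> int:
        return len(self.node_names)

    @property
    def n_edges(self) -> int:
        iu = np.triu_indices(self.p, k=1)
        return int(np.sum(np.abs(self.W[iu]) > EDGE_TOL))

    def edge_list(self) -> list[tuple[str, str, float]]:
        """Nonzero upper-triangle edges as (node_i, node_j, weight)."""
        out = []
        for i in range(self.p):
            for j in range(i + 1, self.p):
                if abs(self.W[i, j]) > EDGE_TOL:
                    out.append((self.node_names[i], self.node_names[j], float(self.W[i, j])))
        return out


@dataclass
class NetworkConfig:
    """Tunable knobs of the estimation chain."""

    method: str = "pearson"  # or "spearman"
    gamma: float = 0.5
    n_lambda: int = 100
    min_ratio: float = 0.01
    refit: bool = False  # unpenalized MLE on the selected graph
    max_iter: int = 500

    def __post_init__(self) -> None:
        if self.method not in ("pearson", "spearman"):
            raise EstimationError(f"unknown correlation method {self.method!r}")
        if self.gamma < 0:
            raise EstimationError("gamma must be nonnegative")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def correlation_matrix(
    data: SubscaleDataset | np.ndarray, method: str = "pearson"
) -> CorrelationMatrix:
    """Pairwise correlation matrix of the score table.

    Zero-variance columns are an error (they carry no network
    information and break standardization).  If the matrix is not
    numerically PSD — possible for Spearman on heavily tied data — it is
    repaired by clipping negative eigenvalues at zero and re-standardizing
    to unit diagonal; the repair is recorded and logged.
    """
    X = data.values() if isinstance(data, SubscaleDataset) else np.asarray(data, float)
    n, p = X.shape
    if n < 3:
        raise EstimationError(f"insufficient sample: n={n} < 3")
    variances = X.var(axis=0)
    dead = np.where(variances == 0)[0]
    if dead.size:
        names = (
            [data.variable_names[i] for i in dead]
            if isinstance(data, SubscaleDataset)
            else dead.tolist()
        )
        raise EstimationError(f"zero-variance column(s): {names}")
    if method == "pearson":
        S = np.corrcoef(X, rowvar=False)
    elif method == "spearman":
        S = stats.spearmanr(X).statistic
        S = np.atleast_2d(S)
    else:
        raise EstimationError(f"unknown correlation method {method!r}")
    S = (S + S.T) / 2.0
    np.fill_diagonal(S, 1.0)
    repaired = False
    eigmin = float(np.linalg.eigvalsh(S)[0])
    if eigmin < -1e-8:
        warnings.warn(
            f"correlation matrix not PSD (min eigenvalue {eigmin:.3e}); "
            "applying eigenvalue-clipping repair",
            stacklevel=2,
        )
        w, V = np.linalg.eigh(S)
        S = (V * np.clip(w, 0.0, None)) @ V.T
        d = np.sqrt(np.diag(S))
        S = S / np.outer(d, d)
        S = (S + S.T) / 2.0
        np.fill_diagonal(S, 1.0)
        repaired = True
    return CorrelationMatrix(S=S, method=method, n=n, repaired=repaired)


def lambda_grid(
    S: CorrelationMatrix | np.ndarray, n_lambda: int = 100, min_ratio: float = 0.01
) -> LambdaPath:
    """Log-spaced decreasing penalty grid from lambda_max = max |S_ij|."""
    M = S.S if isinstance(S, CorrelationMatrix) else np.asarray(S, float)
    if n_lambda < 2:
        raise EstimationError("n_lambda must be at least 2")
    if not (0 < min_ratio < 1):
        raise EstimationError("min_ratio must lie in (0, 1)")
    p = M.shape[0]
    off = M[~np.eye(p, dtype=bool)]
    lam_max = float(np.max(np.abs(off))) if off.size else 0.0
    if lam_max <= 0:
        raise EstimationError("empty model at all penalties: all off-diagonals zero")
    lams = np.geomspace(lam_max, lam_max * min_ratio, n_lambda)
    return LambdaPath(lambdas=lams)


def precision_to_pcor(K: np.ndarray) -> np.ndarray:
    """Partial correlations from a precision matrix.

    P_ij = -K_ij / sqrt(K_ii K_jj) off the diagonal; unit diagonal.
    """
    K = np.asarray(K, dtype=float)
    if not np.allclose(K, K.T, atol=1e-8):
        raise EstimationError("precision matrix must be symmetric")
    if np.linalg.eigvalsh(K)[0] <= 0:
        raise EstimationError("precision matrix must be positive definite")
    d = np.sqrt(np.diag(K))
    P = -K / np.outer(d, d)
    np.fill_diagonal(P, 1.0)
    return (P + P.T) / 2.0


def ebic(L: float, E: int, n: int, p: int, gamma: float) -> float:
    """Extended BIC: -2L + E log n + 4 E gamma log p."""
    if E < 0:
        raise EstimationError("edge count must be nonnegative")
    if n < 2 or p < 2:
        raise EstimationError("need n >= 2 and p >= 2")
    if gamma < 0:
        raise EstimationError("gamma must be nonnegative")
    return -2.0 * L + E * np.log(n) + 4.0 * E * gamma * np.log(p)


def _dual_gap(S: np.ndarray, K: np.ndarray, lam: float) -> float:
    """Duality gap of the glasso problem at precision estimate K."""
    p = S.shape[0]
    gap = np.sum(S * K) - p
    gap += lam * (np.abs(K).sum() - np.abs(np.diag(K)).sum())
    return float(gap)


def _admm_glasso(
    S: np.ndarray, lam: float, rho: float = 1.0, max_iter: int = 5000, tol: float = 1e-9
) -> np.ndarray:
    """ADMM solver for the glasso problem (off-diagonal penalty).

    Fallback for the rare instances where coordinate descent stalls
    (notably at near-zero penalties); the eigendecomposition-based K
    update converges for any lam > 0 regardless of conditioning.
    """
    p = S.shape[0]
    Z = np.eye(p)
    U = np.zeros((p, p))
    for _ in range(max_iter):
        w, Q = np.linalg.eigh(rho * (Z - U) - S)
        kw = (w + np.sqrt(w**2 + 4.0 * rho)) / (2.0 * rho)
        K = (Q * kw) @ Q.T
        Z_old = Z
        A = K + U
        Z = np.sign(A) * np.maximum(np.abs(A) - lam / rho, 0.0)
        np.fill_diagonal(Z, np.diag(A))
        U += K - Z
        primal = np.linalg.norm(K - Z)
        dual = rho * np.linalg.norm(Z - Z_old)
        if primal < tol and dual < tol:
            break
    return (K + K.T) / 2.0


def _count_edges(P: np.ndarray) -> int:
    iu = np.triu_indices(P.shape[0], k=1)
    return int(np.sum(np.abs(P[iu]) > EDGE_TOL))


def glasso_path(
    S: CorrelationMatrix, grid: LambdaPath, max_iter: int = 500
) -> PathFit:
    """Graphical-lasso solutions along the penalty grid.

    Solutions are warm-started from the previous (larger) penalty, which
    keeps the dense small-lambda end of the path cheap and stable.  A
    penalty whose solve does not converge is retried from cold with a
    quadrupled iteration budget; persistent failure raises — unless a
    prefix of the path already fitted and the input is singular (p > n),
    in which case the path is truncated at the last stable penalty with a
    loud warning (the unpenalized end of the path does not exist for
    rank-deficient inputs).
    """
    n, p = S.n, S.p
    precisions: list[np.ndarray] = []
    pcors: list[np.ndarray] = []
    edge_counts = np.empty(grid.n_lambda, dtype=int)
    logliks = np.empty(grid.n_lambda)
    singular = np.linalg.eigvalsh(S.S)[0] < 1e-10
    n_fitted = grid.n_lambda
    cov_init = None
    for k, lam in enumerate(grid.lambdas):
        K = None
        failure: Exception | None = None
        for init, iters in ((cov_init, max_iter), (None, 4 * max_iter)):
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always", ConvergenceWarning)
                try:
                    cov, K = _solve_glasso(S.S, float(lam), init, iters)
                except FloatingPointError as exc:
                    failure = GlassoConvergenceError(
                        f"graphical lasso failed at lambda={lam:.6g}: {exc}"
                    )
                    K = None
                    continue
            if not any(issubclass(w.category, ConvergenceWarning) for w in caught):
                break
        else:
            if K is not None:
                # coordinate descent stalled; try the ADMM fallback and keep
                # whichever iterate has the smaller duality gap
                gap = _dual_gap(S.S, K, float(lam))
                K_admm = _admm_glasso(S.S, float(lam))
                gap_admm = _dual_gap(S.S, K_admm, float(lam))
                if abs(gap_admm) < abs(gap) and np.linalg.eigvalsh(K_admm)[0] > 0:
                    K, cov, gap = K_admm, np.linalg.inv(K_admm), gap_admm
                if abs(gap) > GAP_TOL:
                    failure = GlassoConvergenceError(
                        f"graphical lasso did not converge at lambda={lam:.6g} "
                        f"within {4 * max_iter} iterations (dual gap {gap:.3e})"
                    )
                    K = None
        if K is not None:
            K = (K + K.T) / 2.0
            if np.linalg.eigvalsh(K)[0] <= 0:
                failure = GlassoConvergenceError(
                    f"non-positive-definite precision at lambda={lam:.6g}"
                )
                K = None
        if K is None:
            if singular and k > 0:
                warnings.warn(
                    f"rank-deficient input: truncating penalty path at "
                    f"lambda={grid.lambdas[k - 1]:.6g} ({k} of {grid.n_lambda} "
                    f"penalties fitted); {failure}",
                    stacklevel=2,
                )
                n_fitted = k
                break
            raise failure
        cov_init = cov
        P = precision_to_pcor(K)
        W = P.copy()
        np.fill_diagonal(W, 0.0)
        # zero out numerically-dead entries so edge counts are solver-independent
        W[np.abs(W) <= EDGE_TOL] = 0.0
        precisions.append(K)
        pcors.append(W + np.eye(p))
        edge_counts[k] = _count_edges(P)
        sign, logdet = np.linalg.slogdet(K)
        logliks[k] = (n / 2.0) * (logdet - np.trace(S.S @ K))
    return PathFit(
        lambdas=np.asarray(grid.lambdas, float)[:n_fitted],
        precisions=precisions,
        pcors=pcors,
        edge_counts=edge_counts[:n_fitted],
        logliks=logliks[:n_fitted],
        n=n,
        p=p,
    )


def select_network(
    fit: PathFit,
    gamma: float = 0.5,
    node_names: Sequence[str] | None = None,
    group_label: str = "",
) -> RegularizedNetwork:
    """Pick the penalty minimizing EBIC; ties go to the larger penalty.

    The grid is stored in decreasing order, so the first argmin is the
    sparser (larger-lambda) model.
    """
    if fit.lambdas.size == 0:
        raise EstimationError("empty path fit")
    scores = fit.ebics(gamma)
    k = int(np.argmin(scores))
    W = fit.pcors[k].copy()
    np.fill_diagonal(W, 0.0)
    names = list(node_names) if node_names is not None else [f"v{i:02d}" for i in range(fit.p)]
    return RegularizedNetwork(
        node_names=names,
        W=W,
        lambda_selected=float(fit.lambdas[k]),
        gamma=float(gamma),
        n=fit.n,
        group_label=group_label,
        metadata={
            "ebic": float(scores[k]),
            "edge_count": int(fit.edge_counts[k]),
            "lambda_index": k,
        },
    )


def _refit_mle(S: np.ndarray, support: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Unpenalized Gaussian MLE constrained to a fixed edge support.

    Classic iterative proportional scaling: cycle over nodes, solving the
    local regression restricted to each node's neighborhood, until the
    covariance matches S on the support.
    """
    p = S.shape[0]
    Sigma = S.copy()
    mask = support | np.eye(p, dtype=bool)
    for _ in range(1000):
        Sigma_old = Sigma.copy()
        for j in range(p):
            nb = np.where(mask[j] & (np.arange(p) != j))[0]
            if nb.size == 0:
                continue
            S11 = Sigma[np.ix_(nb, nb)]
            s12 = S[np.ix_(nb, [j])]
            beta = np.linalg.solve(S11, s12)
            Sigma[nb, j] = (S11 @ beta).ravel()
            Sigma[j, nb] = Sigma[nb, j]
        if np.max(np.abs(Sigma - Sigma_old)) < tol:
            break
    K = np.linalg.inv(Sigma)
    K[~mask] = 0.0
    return (K + K.T) / 2.0


def estimate_network(
    data: SubscaleDataset | np.ndarray,
    config: NetworkConfig | None = None,
    group_label: str | None = None,
) -> RegularizedNetwork:
    """Full chain: correlations -> penalty grid -> glasso -> EBIC selection."""
    config = config or NetworkConfig()
    S = correlation_matrix(data, method=config.method)
    grid = lambda_grid(S, n_lambda=config.n_lambda, min_ratio=config.min_ratio)
    fit = glasso_path(S, grid, max_iter=config.max_iter)
    names = data.variable_names if isinstance(data, SubscaleDataset) else None
    label = group_label
    if label is None:
        label = data.group_label if isinstance(data, SubscaleDataset) else ""
    net = select_network(fit, gamma=config.gamma, node_names=names, group_label=label)
    if config.refit and net.n_edges > 0:
        support = np.abs(net.W) > EDGE_TOL
        K = _refit_mle(S.S, support)
        W = precision_to_pcor(K)
        np.fill_diagonal(W, 0.0)
        W[~support] = 0.0
        net.W = (W + W.T) / 2.0
        net.metadata["refit"] = True
    net.metadata.update(
        {
            "method": config.method,
            "n_lambda": config.n_lambda,
            "min_ratio": config.min_ratio,
            "psd_repaired": S.repaired,
        }
    )
    return net
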