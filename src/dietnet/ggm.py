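"""Sparse Gaussian graphical model estimation and dietary-network extraction.

The dependence structure among food-group intakes is modelled as a Gaussian
graphical model: a zero in the precision (inverse covariance) matrix of the
standardized intakes means the two groups are conditionally independent given
all others.  The precision matrix is estimated by the graphical lasso —
L1-penalized Gaussian maximum likelihood,

    maximize  log det(O) - trace(S O) - lam * sum_{i != j} |O_ij|,

with the diagonal unpenalized and S the sample correlation matrix of the
standardized intakes.  The solver is an ADMM splitting scheme (eigendecomposition
step for the likelihood, elementwise soft-threshold for the penalty), run to a
tight primal/dual tolerance and verified against the KKT stationarity
conditions.

Edges are the nonzero off-diagonals of the estimate; their weights are partial
correlations rho_ij = -O_ij / sqrt(O_ii O_jj).  Connected components with at
least ``min_network_size`` nodes form dietary networks; |rho| >= ``strong_threshold``
flags an edge as strong (a display/interpretation label, not an adjacency
filter).

Penalty selection defaults to EBIC with gamma = 0.5 evaluated on the
support-constrained refitted MLE for each candidate lambda; see
``select_lambda``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConvergenceError, NotPositiveDefiniteError, ValidationError

__all__ = [
    "GGMConfig",
    "PrecisionMatrix",
    "Network",
    "DietaryNetworkSet",
    "SelectionResult",
    "standardize",
    "sample_correlation",
    "estimate_precision",
    "select_lambda",
    "precision_to_partial",
    "extract_networks",
    "kkt_violation",
]


@dataclass
class GGMConfig:
    """Tuning knobs for precision estimation and network extraction.

    lam: penalty value, or "auto" to select via ``select_lambda``.
    lam_grid: candidate penalties for selection (default: 15 log-spaced values
        from lam_max down to lam_max/50, where lam_max is the largest absolute
        off-diagonal sample correlation).
    criterion: "ebic" or "cv" (k-fold held-out Gaussian log-likelihood).
    ebic_gamma: EBIC sparsity weight in [0, 1].
    refit_for_selection: evaluate the selection criterion on the
        support-constrained refitted MLE rather than the shrunken estimate.
    strong_threshold: |partial correlation| labelled "strong" (tau).
    strong_edge_filter: if True, drop edges below tau before components are
        formed (off by default: adjacency is the glasso sparsity pattern).
    """

    lam: float | str = "auto"
    lam_grid: np.ndarray | None = None
    n_grid: int = 15
    criterion: str = "ebic"
    ebic_gamma: float = 0.5
    cv_folds: int = 5
    tol: float = 1e-8
    max_iter: int = 5000
    strong_threshold: float = 0.30
    strong_edge_filter: bool = False
    min_network_size: int = 3
    zero_tol: float = 1e-8

    def __post_init__(self) -> None:
        if isinstance(self.lam, (int, float)) and self.lam < 0:
            raise ValidationError("penalty lam must be >= 0")
        if not 0 < self.strong_threshold < 1:
            raise ValidationError("strong_threshold must lie in (0, 1)")
        if self.min_network_size < 3:
            raise ValidationError("min_network_size must be >= 3")
        if not 0 <= self.ebic_gamma <= 1:
            raise ValidationError("ebic_gamma must lie in [0, 1]")


@dataclass
class PrecisionMatrix:
    """Estimated sparse precision matrix with convergence diagnostics."""

    matrix: pd.DataFrame
    lam: float
    n_iter: int
    kkt_max_violation: float
    converged: bool

    @property
    def groups(self) -> list[str]:
        return list(self.matrix.columns)

    def values(self) -> np.ndarray:
        return self.matrix.to_numpy()


@dataclass
class Network:
    """One dietary network: a connected set of >= 3 food groups."""

    network_id: str
    nodes: tuple[str, ...]
    # (node_a, node_b, partial_correlation, strong_flag), lexicographic edges
    edges: tuple[tuple[str, str, float, bool], ...]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degree(self) -> dict[str, int]:
        deg = {n: 0 for n in self.nodes}
        for a, b, _, _ in self.edges:
            deg[a] += 1
            deg[b] += 1
        return deg

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for a, b, rho, strong in self.edges:
            g.add_edge(a, b, partial_correlation=rho, strong=strong)
        return g


@dataclass
class DietaryNetworkSet:
    """Networks plus the leftover components that were too small to count."""

    networks: list[Network]
    leftovers: list[tuple[str, ...]]  # components with < min_network_size nodes

    def __iter__(self):
        return iter(self.networks)

    def __len__(self) -> int:
        return len(self.networks)

    def edge_table(self) -> pd.DataFrame:
        rows = [
            (net.network_id, a, b, rho, strong)
            for net in self.networks
            for a, b, rho, strong in net.edges
        ]
        return pd.DataFrame(
            rows,
            columns=["network_id", "node1", "node2", "partial_correlation", "strong_flag"],
        )

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        for net in self.networks:
            for a, b, rho, strong in net.edges:
                g.add_edge(a, b, partial_correlation=rho, strong=strong, network_id=net.network_id)
        return g


@dataclass
class SelectionResult:
    lam: float
    criterion: str
    table: pd.DataFrame  # full curve: lam, n_edges, loglik, score

    def __float__(self) -> float:
        return float(self.lam)


# ---------------------------------------------------------------------------
# standardization


def standardize(intakes: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Z-score every food-group column to mean 0 and population SD 1.

    Returns the standardized matrix and a (mean, sd) parameter table so the
    same transform can be re-applied to new subjects.
    """
    values = intakes.to_numpy(dtype=float)
    mean = values.mean(axis=0)
    sd = values.std(axis=0)  # population convention (divide by n)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        names = ", ".join(intakes.columns[i] for i in zero)
        raise ValidationError(f"zero-variance food group(s): {names}")
    z = (values - mean) / sd
    zdf = pd.DataFrame(z, index=intakes.index, columns=intakes.columns)
    params = pd.DataFrame({"mean": mean, "sd": sd}, index=intakes.columns)
    return zdf, params


def sample_correlation(z: pd.DataFrame) -> np.ndarray:
    """Population-convention sample correlation of standardized data."""
    x = z.to_numpy(dtype=float)
    x = (x - x.mean(0)) / x.std(0)
    return (x.T @ x) / x.shape[0]


# ---------------------------------------------------------------------------
# graphical lasso (ADMM)


def _admm_glasso(
    S: np.ndarray,
    lam: float | np.ndarray,
    tol: float,
    max_iter: int,
    rho: float = 1.0,
) -> tuple[np.ndarray, int, bool]:
    """ADMM solver for the off-diagonal-penalized graphical lasso.

    ``lam`` may be a scalar or an elementwise penalty matrix (used for the
    support-constrained refit).  Returns the sparse iterate Z, the iteration
    count and a convergence flag.
    """
    p = S.shape[0]
    L = np.full((p, p), float(lam)) if np.isscalar(lam) else np.asarray(lam, dtype=float)
    np.fill_diagonal(L, 0.0)
    Z = np.linalg.inv(S + 0.1 * np.eye(p))
    U = np.zeros((p, p))
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        d, Q = np.linalg.eigh(rho * (Z - U) - S)
        theta = (d + np.sqrt(d * d + 4.0 * rho)) / (2.0 * rho)
        omega = (Q * theta) @ Q.T
        A = omega + U
        Z_new = np.sign(A) * np.maximum(np.abs(A) - L / rho, 0.0)
        np.fill_diagonal(Z_new, np.diag(A))
        r_primal = np.linalg.norm(omega - Z_new)
        r_dual = rho * np.linalg.norm(Z_new - Z)
        Z = Z_new
        U = U + omega - Z
        if r_primal < tol * p and r_dual < tol * p:
            converged = True
            break
    return Z, it, converged


def kkt_violation(omega: np.ndarray, S: np.ndarray, lam: float, zero_tol: float = 1e-8) -> float:
    """Maximum violation of the glasso stationarity conditions.

    For the off-diagonal-penalized objective the optimum satisfies
    W - S = lam * sign(O_ij) on active entries, |W_ij - S_ij| <= lam on zero
    entries, and W_ii = S_ii on the diagonal, where W = O^{-1}.
    """
    W = np.linalg.inv(omega)
    G = W - S
    p = S.shape[0]
    off = ~np.eye(p, dtype=bool)
    active = off & (np.abs(omega) > zero_tol)
    inactive = off & ~active
    v = 0.0
    if active.any():
        v = max(v, np.max(np.abs(G[active] - lam * np.sign(omega[active]))))
    if inactive.any():
        v = max(v, np.max(np.maximum(np.abs(G[inactive]) - lam, 0.0)))
    v = max(v, np.max(np.abs(np.diag(G))))
    return float(v)


def estimate_precision(
    z: pd.DataFrame,
    lam: float,
    config: GGMConfig | None = None,
) -> PrecisionMatrix:
    """Estimate the sparse precision matrix of standardized intakes.

    At ``lam = 0`` the estimate is the exact inverse of the sample correlation
    matrix; otherwise the ADMM solver is run and the result checked against
    the KKT conditions.
    """
    config = config or GGMConfig()
    if lam < 0:
        raise ValidationError("penalty lam must be >= 0")
    if len(z) < 2:
        raise ValidationError("need at least 2 subjects to estimate a precision matrix")
    S = sample_correlation(z)
    groups = list(z.columns)
    p = S.shape[0]
    if lam == 0:
        if np.linalg.eigvalsh(S).min() <= 0:
            raise NotPositiveDefiniteError(
                "sample correlation matrix is singular; lam = 0 requires n > p"
            )
        omega = np.linalg.inv(S)
        omega = (omega + omega.T) / 2
        mat = pd.DataFrame(omega, index=groups, columns=groups)
        return PrecisionMatrix(mat, 0.0, 0, kkt_violation(omega, S, 0.0), True)
    omega, n_iter, converged = _admm_glasso(S, lam, config.tol, config.max_iter)
    omega[np.abs(omega) < config.zero_tol] = 0.0
    omega = (omega + omega.T) / 2
    viol = kkt_violation(omega, S, lam, config.zero_tol)
    if not converged:
        raise ConvergenceError(
            f"graphical lasso did not converge at lam={lam:.6g} within "
            f"{config.max_iter} iterations (KKT violation {viol:.3g})"
        )
    if np.linalg.eigvalsh(omega).min() <= 0:
        raise NotPositiveDefiniteError("estimated precision matrix is not positive definite")
    mat = pd.DataFrame(omega, index=groups, columns=groups)
    return PrecisionMatrix(mat, float(lam), n_iter, viol, converged)


def _support_refit(S: np.ndarray, support: np.ndarray, tol: float, max_iter: int) -> np.ndarray:
    """Gaussian MLE constrained to a fixed zero pattern (huge penalty off-support)."""
    penalty = np.where(support, 0.0, 1e6)
    omega, _, _ = _admm_glasso(S, penalty, tol, max_iter)
    return omega


def _gauss_loglik(omega: np.ndarray, S: np.ndarray, n: int) -> float:
    sign, logdet = np.linalg.slogdet(omega)
    if sign <= 0:
        return -np.inf
    return 0.5 * n * (logdet - float(np.trace(S @ omega)))


def default_lambda_grid(S: np.ndarray, n_grid: int = 15) -> np.ndarray:
    lam_max = float(np.max(np.abs(S - np.diag(np.diag(S)))))
    return np.geomspace(lam_max, lam_max / 50.0, n_grid)


def select_lambda(z: pd.DataFrame, config: GGMConfig | None = None) -> SelectionResult:
    """Choose the glasso penalty on a grid.

    "ebic" (default): EBIC(lam) = -2 loglik + k log n + 4 gamma k log p with
    k the number of nonzero upper-triangle edges.  The log-likelihood is
    evaluated at the MLE refitted on the selected support
    (``refit_for_selection``), which removes the shrinkage bias that otherwise
    drags the criterion toward dense solutions; set
    ``GGMConfig(refit_for_selection=False)`` for the penalized-likelihood
    variant.

    "cv": k-fold held-out Gaussian log-likelihood with contiguous,
    deterministic folds.

    The full criterion curve is returned for audit.
    """
    config = config or GGMConfig()
    n, p = z.shape
    S = sample_correlation(z)
    grid = config.lam_grid if config.lam_grid is not None else default_lambda_grid(S, config.n_grid)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValidationError("lambda grid is empty")
    rows = []
    fits: list[tuple[float, float]] = []  # (score, lam)
    if config.criterion == "ebic":
        # a looser solver tolerance is adequate for support identification
        sel_tol = max(config.tol, 1e-7)
        for lam in grid:
            omega, _, ok = _admm_glasso(S, lam, sel_tol, config.max_iter)
            if not ok:
                continue
            support = np.abs(omega) > config.zero_tol
            k = int(support[np.triu_indices(p, 1)].sum())
            if getattr(config, "refit_for_selection", True):
                omega_eval = _support_refit(S, support, sel_tol, config.max_iter)
            else:
                omega_eval = omega
            ll = _gauss_loglik(omega_eval, S, n)
            score = -2.0 * ll + k * np.log(n) + 4.0 * config.ebic_gamma * k * np.log(p)
            rows.append((lam, k, ll, score))
            fits.append((score, lam))
    elif config.criterion == "cv":
        folds = np.array_split(np.arange(n), config.cv_folds)
        zv = z.to_numpy(dtype=float)
        for lam in grid:
            ll_total, k = 0.0, 0
            ok_all = True
            for test_idx in folds:
                train_idx = np.setdiff1d(np.arange(n), test_idx)
                ztr = zv[train_idx]
                ztr = (ztr - ztr.mean(0)) / ztr.std(0)
                Str = (ztr.T @ ztr) / len(ztr)
                omega, _, ok = _admm_glasso(Str, lam, max(config.tol, 1e-7), config.max_iter)
                ok_all &= ok
                zte = zv[test_idx]
                zte = (zte - zte.mean(0)) / zte.std(0)
                Ste = (zte.T @ zte) / len(zte)
                ll_total += _gauss_loglik(omega, Ste, len(test_idx))
                k = int((np.abs(omega) > config.zero_tol)[np.triu_indices(p, 1)].sum())
            if not ok_all:
                continue
            rows.append((lam, k, ll_total, -ll_total))
            fits.append((-ll_total, lam))
    else:
        raise ValidationError(f"unknown selection criterion {config.criterion!r}")
    if not fits:
        raise ConvergenceError("no penalty in the grid produced a converged fit")
    table = pd.DataFrame(rows, columns=["lam", "n_edges", "loglik", "score"])
    best_score, best_lam = min(fits)
    return SelectionResult(float(best_lam), config.criterion, table)


# ---------------------------------------------------------------------------
# partial correlations and network extraction


def precision_to_partial(precision: PrecisionMatrix | pd.DataFrame) -> pd.DataFrame:
    """Convert a precision matrix to partial correlations.

    rho_ij = -O_ij / sqrt(O_ii O_jj) off the diagonal, 1 on it; the sparsity
    pattern of the precision matrix is inherited exactly.
    """
    mat = precision.matrix if isinstance(precision, PrecisionMatrix) else precision
    omega = mat.to_numpy(dtype=float)
    diag = np.diag(omega)
    if np.any(diag <= 0):
        bad = mat.columns[np.flatnonzero(diag <= 0)]
        raise NotPositiveDefiniteError(
            f"precision diagonal must be strictly positive; offending: {', '.join(bad)}"
        )
    d = 1.0 / np.sqrt(diag)
    rho = -omega * np.outer(d, d)
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=mat.index, columns=mat.columns)


def extract_networks(rho: pd.DataFrame, config: GGMConfig | None = None) -> DietaryNetworkSet:
    """Partition the partial-correlation graph into dietary networks.

    Adjacency is the nonzero pattern (the glasso support); connected components
    with >= ``min_network_size`` nodes become networks, smaller ones are logged
    as leftovers.  Networks are ordered by node count descending, ties by the
    alphabetically first node.
    """
    config = config or GGMConfig()
    groups = list(rho.columns)
    vals = rho.to_numpy(dtype=float)
    g = nx.Graph()
    g.add_nodes_from(groups)
    p = len(groups)
    tau = config.strong_threshold
    for i in range(p):
        for j in range(i + 1, p):
            v = vals[i, j]
            if abs(v) > config.zero_tol:
                if config.strong_edge_filter and abs(v) < tau:
                    continue
                g.add_edge(groups[i], groups[j], rho=float(v))
    comps = [tuple(sorted(c)) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    networks: list[Network] = []
    leftovers: list[tuple[str, ...]] = []
    for comp in comps:
        if len(comp) < config.min_network_size:
            leftovers.append(comp)  # singletons and pairs
            continue
        edges = sorted(
            (min(a, b), max(a, b), g.edges[a, b]["rho"], abs(g.edges[a, b]["rho"]) >= tau)
            for a, b in g.subgraph(comp).edges
        )
        networks.append(
            Network(
                network_id=f"network_{len(networks) + 1}",
                nodes=comp,
                edges=tuple(edges),
            )
        )
    return DietaryNetworkSet(networks=networks, leftovers=leftovers)
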