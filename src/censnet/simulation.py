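"""Ground-truth networks and network-structured censored survival data.

The generator draws an undirected graph, builds a diagonally dominant
precision matrix on it, converts it to a correlation-scaled covariance, and
draws log-normal event times whose log follows N(0, Sigma).  Censoring times
are independent exponentials, so the censoring rate is driven by the
exponential rate parameter ``lam``: with unit log-variance and ``lam = 1``
roughly 60% of observations are censored.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Any, Mapping

import networkx as nx
import numpy as np

from .data_model import SurvivalMatrix

__all__ = [
    "NetworkSpec",
    "SimConfig",
    "SimulatedData",
    "generate_network",
    "build_precision",
    "precision_to_covariance",
    "generate_data",
]


@dataclasses.dataclass
class NetworkSpec:
    """Undirected ground-truth graph whose edges are the conditional positives."""

    kind: str
    n_nodes: int
    adjacency: np.ndarray  # (J, J) symmetric binary, zero diagonal
    params: dict[str, Any]
    seed: int

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if not np.array_equal(a, a.T) or np.any(np.diag(a) != 0):
            raise ValueError("adjacency must be symmetric with a zero diagonal")
        if not np.all(np.isin(a, (0, 1))):
            raise ValueError("adjacency must be binary")

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum() // 2)


@dataclasses.dataclass
class SimConfig:
    """All parameters of one simulated dataset.

    ``sigma_tilde`` is the partial-correlation constant placed on network
    edges of the initial precision matrix (0.8 unless stated otherwise) and
    ``lam`` the exponential censoring rate parameter.
    """

    n_samples: int
    n_events: int
    sigma_tilde: float = 0.8
    lam: float = 1.0
    seed: int = 0
    network_kind: str = "scale_free"
    network_params: Mapping[str, Any] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_samples < 2 or self.n_events < 2:
            raise ValueError("need n_samples >= 2 and n_events >= 2")
        if not 0 < self.sigma_tilde < 1:
            raise ValueError("sigma_tilde must be in (0, 1)")
        if self.lam <= 0:
            raise ValueError("lam must be positive")


@dataclasses.dataclass
class SimulatedData:
    """True times, censoring times, composed survival data and the truth."""

    true_times: np.ndarray      # (N, J)
    censor_times: np.ndarray    # (N, J)
    sm: SurvivalMatrix
    sigma: np.ndarray           # (J, J) true covariance of log T
    network: NetworkSpec


def generate_network(
    kind: str,
    n_nodes: int,
    params: Mapping[str, Any] | None = None,
    seed: int = 0,
) -> NetworkSpec:
    """Draw a ground-truth graph.

    Kinds
    -----
    ``scale_free``
        Preferential attachment adding one edge per new node, hence exactly
        ``J - 1`` edges.
    ``random``
        Independent edges with probability ``p`` (default ``2/J``).
    ``small_world``
        Ring lattice with ``neighbors`` per side (default 1, i.e. J edges)
        rewired with probability ``rewire`` (default 0.15).
    """
    params = dict(params or {})
    if kind == "scale_free":
        g = nx.barabasi_albert_graph(n_nodes, 1, seed=seed)
    elif kind == "random":
        p = params.setdefault("p", 2.0 / n_nodes)
        g = nx.gnp_random_graph(n_nodes, p, seed=seed)
    elif kind == "small_world":
        neighbors = params.setdefault("neighbors", 1)
        rewire = params.setdefault("rewire", 0.15)
        g = nx.watts_strogatz_graph(n_nodes, 2 * neighbors, rewire, seed=seed)
    else:
        raise ValueError(f"unknown network kind {kind!r}")
    adjacency = nx.to_numpy_array(g, nodelist=range(n_nodes), dtype=int)
    return NetworkSpec(
        kind=kind, n_nodes=n_nodes, adjacency=adjacency, params=params, seed=seed
    )


def build_precision(
    net: NetworkSpec, sigma_tilde: float = 0.8
) -> tuple[np.ndarray, np.ndarray]:
    """Initial precision on the graph, rescaled to diagonal dominance.

    Start from ``P = I + sigma_tilde * adjacency``; divide each off-diagonal
    entry of row i by ``2 * (sum_j |p_ij| - 1)`` (twice the row's off-diagonal
    absolute sum, so every rescaled row's off-diagonal sum is exactly 1/2);
    symmetrize by averaging with the transpose.  Around high-degree hubs the
    averaging can re-inflate rows, so the symmetrized matrix is usually, but
    not always, positive definite; :func:`generate_data` redraws the graph
    when it is not.  Isolated nodes (zero off-diagonal row sum) are removed
    first and reported for later reinsertion.

    Returns
    -------
    (A, isolated)
        The symmetrized matrix on the non-isolated block, and the sorted
        indices of isolated nodes.
    """
    adj = net.adjacency
    degree = adj.sum(axis=1)
    isolated = np.flatnonzero(degree == 0)
    keep = np.flatnonzero(degree > 0)
    if keep.size == 0:
        return np.eye(0), isolated
    p = np.eye(keep.size) + sigma_tilde * adj[np.ix_(keep, keep)]
    row_off = np.abs(p).sum(axis=1) - 1.0  # diagonal entries are 1
    rescaled = p / (2.0 * row_off)[:, None]
    np.fill_diagonal(rescaled, 1.0)
    return 0.5 * (rescaled + rescaled.T), isolated


def precision_to_covariance(
    a: np.ndarray, isolated: np.ndarray, n_nodes: int | None = None
) -> np.ndarray:
    """Correlation-scaled covariance ``Sigma_ij = A^-1_ij / sqrt(A^-1_ii A^-1_jj)``.

    Isolated nodes are reinserted at their original positions with unit
    variance and zero covariance, keeping ``diag(Sigma) = 1`` throughout.
    """
    isolated = np.asarray(isolated, dtype=int)
    if n_nodes is None:
        n_nodes = a.shape[0] + isolated.size
    if a.shape[0]:
        eig_min = float(np.linalg.eigvalsh(a)[0])
        if eig_min <= 0:
            raise ValueError("precision matrix is not positive definite")
        inv = np.linalg.inv(a)
        d = np.sqrt(np.diag(inv))
        block = inv / np.outer(d, d)
    else:
        block = np.zeros((0, 0))
    keep = np.setdiff1d(np.arange(n_nodes), isolated)
    sigma = np.eye(n_nodes)
    sigma[np.ix_(keep, keep)] = block
    return sigma


def _draw_structure(
    cfg: SimConfig, rng: np.random.Generator, max_attempts: int = 100
) -> tuple[NetworkSpec, np.ndarray]:
    """Draw a network whose rescaled-symmetrized precision is positive definite.

    The construction can turn indefinite around high-degree hubs; such draws
    cannot parameterize a Gaussian and are redrawn (with a warning) from the
    same seed stream, keeping the generator deterministic.
    """
    for attempt in range(max_attempts):
        net_seed = int(rng.integers(2 ** 31))
        net = generate_network(
            cfg.network_kind, cfg.n_events, cfg.network_params, net_seed
        )
        a, isolated = build_precision(net, cfg.sigma_tilde)
        if a.shape[0] == 0 or float(np.linalg.eigvalsh(a)[0]) > 1e-10:
            if attempt:
                warnings.warn(
                    f"redrew the ground-truth network {attempt} time(s) to "
                    "obtain a positive-definite precision matrix"
                )
            return net, precision_to_covariance(a, isolated, cfg.n_events)
    raise RuntimeError(
        "could not draw a positive-definite precision matrix in "
        f"{max_attempts} attempts"
    )


def generate_data(cfg: SimConfig, data_seed: int | None = None) -> SimulatedData:
    """Draw one dataset: ``log T ~ N(0, Sigma)``, ``C_j ~ Exp(lam)`` i.i.d.

    All randomness flows from ``cfg.seed`` through a single generator stream
    (the graph seed is drawn from the same stream), so identical configs give
    bit-identical data.  When ``data_seed`` is given the graph still comes
    from ``cfg.seed`` but times and censoring are drawn from a separate
    stream, which keeps the network fixed across repetitions.
    """
    rng = np.random.default_rng(cfg.seed)
    net, sigma = _draw_structure(cfg, rng)
    if data_seed is not None:
        rng = np.random.default_rng(data_seed)
    chol = np.linalg.cholesky(sigma)
    z = rng.standard_normal((cfg.n_samples, cfg.n_events)) @ chol.T
    true_times = np.exp(z)
    censor_times = rng.exponential(scale=1.0 / cfg.lam, size=(cfg.n_samples, cfg.n_events))
    times = np.minimum(true_times, censor_times)
    status = (true_times <= censor_times).astype(int)
    sm = SurvivalMatrix(
        times=times,
        status=status,
        event_names=[f"event_{j}" for j in range(cfg.n_events)],
    )
    return SimulatedData(
        true_times=true_times,
        censor_times=censor_times,
        sm=sm,
        sigma=sigma,
        network=net,
    )
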