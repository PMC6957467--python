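"""Latent structure of the spatio-temporal injury-mortality model.

The model is a Poisson log-linear regression for monthly death counts in
each state, with

``log rate[s,t] = (a0 + b0 x_t) + (a_state[s] + b_state[s] x_t)
               + (a_month[m] + b_month[m] x_t) + zeta[s,m] + psi[s,m] x_t
               + nu[t] + gamma[m] * anomaly[s,t] + eps[s,t]``

where ``m = month(t)`` and ``x_t`` is the overall time covariate (month
index centred at the series midpoint, in units of months).  The random
effect blocks and their priors are:

================  =====================================  ==================
block             prior                                  constraint
================  =====================================  ==================
a_state, b_state  BYM: ICAR (structured u) + iid (v)     each sums to zero
a_month, b_month  cyclic first-order random walk (RW1)   sums to zero
zeta, psi         iid Gaussian (type-I interactions)     each sums to zero
nu                RW1 over overall time                  sums to zero
gamma             cyclic RW1 across months               *unconstrained*
eps               iid Gaussian (overdispersion)          unconstrained
================  =====================================  ==================

``gamma[m]`` is the log monthly death-rate ratio per 1 deg C of anomaly; it
is smoothed across months by the cyclic RW1 but left unconstrained so its
overall level (the average anomaly effect) is identified by the data.

Each random-effect precision carries a Gamma(shape=1, rate=0.001) hyperprior
(equivalently a log-gamma prior on the log precision); the common slope has
a N(0, 1000) prior and the common intercept an (effectively) flat prior,
implemented as N(0, 1e6) for numerical convenience.

Sum-to-zero constraints are imposed by reparameterisation: a constrained
block of size n is represented by n-1 free coordinates z with x = A z,
A = [I; -1'], so every represented value satisfies the constraint exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import numpy as np
import scipy.sparse as sp
from scipy.special import gammaln

from .errors import ValidationError

__all__ = [
    "ModelSpec",
    "LatentState",
    "build_cyclic_rw1_precision",
    "build_rw1_precision",
    "build_icar_precision",
    "time_covariate",
    "linear_predictor",
    "linear_predictor_matrix",
    "log_joint",
]


# ---------------------------------------------------------------------------
# Structure (precision) matrices
# ---------------------------------------------------------------------------

def build_cyclic_rw1_precision(n: int) -> np.ndarray:
    """Structure matrix of a cyclic first-order random walk on n points.

    Circulant with 2 on the diagonal and -1 for the two cyclic neighbours
    (so point n is adjacent to point 1).  Rank n-1; the null space is the
    constant vector.
    """
    if n < 3:
        raise ValidationError("cyclic RW1 needs n >= 3 (cycle undefined below)")
    R = 2.0 * np.eye(n)
    idx = np.arange(n)
    R[idx, (idx + 1) % n] = -1.0
    R[idx, (idx - 1) % n] = -1.0
    return R


def build_rw1_precision(n: int) -> np.ndarray:
    """Structure matrix of a (non-cyclic) first-order random walk: the
    path-graph Laplacian.  Rank n-1."""
    if n < 2:
        raise ValidationError("RW1 needs n >= 2")
    R = np.zeros((n, n))
    i = np.arange(n - 1)
    R[i, i] += 1.0
    R[i + 1, i + 1] += 1.0
    R[i, i + 1] -= 1.0
    R[i + 1, i] -= 1.0
    return R


def build_icar_precision(adjacency: nx.Graph, nodelist: Optional[list] = None) -> np.ndarray:
    """ICAR structure matrix (graph Laplacian) of a state adjacency graph.

    Diagonal holds node degrees, off-diagonals are -1 for neighbours.  Rank
    is n minus the number of connected components.  An isolated node leaves
    its structured effect unidentified (it is still handled by the
    sum-to-zero constraint and the unstructured BYM component); this is
    reported as a warning, not an error.
    """
    if adjacency.number_of_edges() < 1:
        raise ValidationError("adjacency graph has no edges")
    if any(adjacency.has_edge(u, u) for u in adjacency.nodes):
        raise ValidationError("adjacency graph has self-loops")
    isolated = [u for u, d in adjacency.degree() if d == 0]
    if isolated:
        warnings.warn(
            f"isolated nodes in adjacency graph: {isolated}; their structured "
            "spatial effect is unidentified",
            stacklevel=2,
        )
    L = nx.laplacian_matrix(adjacency, nodelist=nodelist).toarray().astype(float)
    return L


def time_covariate(n_times: int) -> np.ndarray:
    """Overall time covariate: month index centred at the series midpoint."""
    t = np.arange(n_times, dtype=float)
    return t - (n_times - 1) / 2.0


# ---------------------------------------------------------------------------
# Model specification and latent state
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """Complete specification of the latent structure.

    Parameters
    ----------
    adjacency
        State contiguity graph (symmetric, no self-loops).
    n_times
        Total number of months in the series (n_years * 12).
    state_labels
        Node order used for all state-indexed arrays; defaults to sorted
        graph nodes.
    hyper_shape, hyper_rate
        Gamma hyperprior on every random-effect precision (defaults 1 and
        0.001: the weakly informative log-gamma prior on log precision).
    slope_prior_var
        Variance of the N(0, .) prior on the common slope b0.
    intercept_prior_var
        Variance standing in for the flat prior on the common intercept.
    components
        Which random-effect groups are active.  Disabling everything except
        the fixed effects and the anomaly term reduces the model to a plain
        Poisson GLM in (time, anomaly).
    gamma_mode
        ``"monthly"``: 12 coefficients under a cyclic RW1 prior (the full
        model).  ``"common"``: a single anomaly coefficient with a
        N(0, slope_prior_var) prior (used for reduced/oracle instances).
    fixed_log_precisions
        Map block name -> fixed log precision.  Fixed blocks drop out of the
        hyperparameter posterior.
    """

    adjacency: nx.Graph
    n_times: int
    state_labels: Optional[list] = None
    hyper_shape: float = 1.0
    hyper_rate: float = 0.001
    slope_prior_var: float = 1000.0
    intercept_prior_var: float = 1.0e6
    components: dict = field(
        default_factory=lambda: {
            "spatial": True,        # a_state, b_state (BYM)
            "seasonal": True,       # a_month, b_month (cyclic RW1)
            "interaction": True,    # zeta, psi (type-I iid)
            "time_rw": True,        # nu (RW1 over months)
            "anomaly": True,        # gamma
            "overdispersion": True, # eps
        }
    )
    gamma_mode: str = "monthly"
    fixed_log_precisions: dict = field(default_factory=dict)
    n_months: int = 12

    def __post_init__(self):
        if self.hyper_shape <= 0 or self.hyper_rate <= 0:
            raise ValidationError("hyperprior shape and rate must be positive")
        A = nx.to_scipy_sparse_array(self.adjacency)
        if (A != A.T).nnz:
            raise ValidationError("adjacency must be symmetric")
        if self.state_labels is None:
            self.state_labels = sorted(self.adjacency.nodes)
        if self.n_times % self.n_months:
            raise ValidationError("n_times must be a whole number of years")
        if self.gamma_mode not in ("monthly", "common"):
            raise ValidationError("gamma_mode must be 'monthly' or 'common'")

    @property
    def n_states(self) -> int:
        return len(self.state_labels)

    def month_of_time(self) -> np.ndarray:
        """Calendar month (1..12) of each overall time index."""
        return np.arange(self.n_times) % self.n_months + 1

    def active_blocks(self) -> list[str]:
        """Names of the random-effect blocks present under ``components``."""
        blocks = []
        if self.components.get("spatial", True):
            blocks += ["u_alpha", "v_alpha", "u_beta", "v_beta"]
        if self.components.get("seasonal", True):
            blocks += ["alpha_month", "beta_month"]
        if self.components.get("interaction", True):
            blocks += ["zeta", "psi"]
        if self.components.get("time_rw", True):
            blocks += ["nu"]
        if self.components.get("anomaly", True) and self.gamma_mode == "monthly":
            blocks += ["gamma"]
        if self.components.get("overdispersion", True):
            blocks += ["epsilon"]
        return blocks


#: block name -> (structure kind, constrained to sum to zero?)
BLOCK_INFO = {
    "u_alpha": ("icar", True),
    "v_alpha": ("iid", True),
    "u_beta": ("icar", True),
    "v_beta": ("iid", True),
    "alpha_month": ("cyclic_rw1", True),
    "beta_month": ("cyclic_rw1", True),
    "zeta": ("iid", True),
    "psi": ("iid", True),
    "nu": ("rw1", True),
    "gamma": ("cyclic_rw1", False),
    "epsilon": ("iid", False),
}


def block_dim(spec: ModelSpec, name: str) -> int:
    S, T, M = spec.n_states, spec.n_times, spec.n_months
    return {
        "u_alpha": S, "v_alpha": S, "u_beta": S, "v_beta": S,
        "alpha_month": M, "beta_month": M,
        "zeta": S * M, "psi": S * M,
        "nu": T, "gamma": M, "epsilon": S * T,
    }[name]


def structure_matrix(spec: ModelSpec, name: str) -> np.ndarray:
    """Dense structure matrix R of a block's Gaussian prior (x' R x form)."""
    kind, _ = BLOCK_INFO[name]
    n = block_dim(spec, name)
    if kind == "iid":
        return np.eye(n)
    if kind == "cyclic_rw1":
        return build_cyclic_rw1_precision(n)
    if kind == "rw1":
        return build_rw1_precision(n)
    if kind == "icar":
        return build_icar_precision(spec.adjacency, nodelist=spec.state_labels)
    raise ValueError(kind)


def structure_rank(spec: ModelSpec, name: str) -> int:
    kind, _ = BLOCK_INFO[name]
    n = block_dim(spec, name)
    if kind == "iid":
        return n
    if kind in ("cyclic_rw1", "rw1"):
        return n - 1
    # ICAR: n minus number of connected components
    return n - nx.number_connected_components(spec.adjacency)


@dataclass
class LatentState:
    """One complete configuration of all latent quantities.

    State-month interaction blocks are stored as (n_states, 12) arrays in
    ``state_labels`` x month order; ``epsilon`` is (n_states, n_times).
    ``gamma`` is a 12-vector (or a scalar in ``gamma_mode="common"``).
    ``log_precisions`` maps block name -> log precision.
    """

    alpha0: float = 0.0
    beta0: float = 0.0
    u_alpha: np.ndarray = None
    v_alpha: np.ndarray = None
    u_beta: np.ndarray = None
    v_beta: np.ndarray = None
    alpha_month: np.ndarray = None
    beta_month: np.ndarray = None
    zeta: np.ndarray = None
    psi: np.ndarray = None
    nu: np.ndarray = None
    gamma: np.ndarray = None
    epsilon: np.ndarray = None
    log_precisions: dict = field(default_factory=dict)

    @classmethod
    def zeros(cls, spec: ModelSpec) -> "LatentState":
        S, T, M = spec.n_states, spec.n_times, spec.n_months
        return cls(
            alpha0=0.0,
            beta0=0.0,
            u_alpha=np.zeros(S), v_alpha=np.zeros(S),
            u_beta=np.zeros(S), v_beta=np.zeros(S),
            alpha_month=np.zeros(M), beta_month=np.zeros(M),
            zeta=np.zeros((S, M)), psi=np.zeros((S, M)),
            nu=np.zeros(T),
            gamma=np.zeros(M) if spec.gamma_mode == "monthly" else 0.0,
            epsilon=np.zeros((S, T)),
            log_precisions={},
        )

    @property
    def alpha_state(self) -> np.ndarray:
        """Combined BYM state intercept deviation (structured + iid)."""
        return self.u_alpha + self.v_alpha

    @property
    def beta_state(self) -> np.ndarray:
        return self.u_beta + self.v_beta

    def block(self, name: str) -> np.ndarray:
        x = getattr(self, name)
        return np.ravel(np.asarray(x, dtype=float))


# ---------------------------------------------------------------------------
# Linear predictor
# ---------------------------------------------------------------------------

def linear_predictor(
    latent: LatentState, spec: ModelSpec, s: int, t: int, anomaly: float
) -> float:
    """Log death rate for state index s at overall time t.

    The exact sum of the eight term groups of the model equation.
    """
    if not (0 <= s < spec.n_states and 0 <= t < spec.n_times):
        raise ValidationError("state or time index out of range")
    x = time_covariate(spec.n_times)[t]
    m = t % spec.n_months
    gamma_m = latent.gamma[m] if np.ndim(latent.gamma) else latent.gamma
    return float(
        (latent.alpha0 + latent.beta0 * x)
        + (latent.alpha_state[s] + latent.beta_state[s] * x)
        + (latent.alpha_month[m] + latent.beta_month[m] * x)
        + latent.zeta[s, m]
        + latent.psi[s, m] * x
        + latent.nu[t]
        + gamma_m * anomaly
        + latent.epsilon[s, t]
    )


def linear_predictor_matrix(
    latent: LatentState, spec: ModelSpec, anomaly: np.ndarray
) -> np.ndarray:
    """Vectorised linear predictor over the full (n_states, n_times) grid."""
    S, T, M = spec.n_states, spec.n_times, spec.n_months
    anomaly = np.asarray(anomaly, dtype=float)
    if anomaly.shape != (S, T):
        raise ValidationError(f"anomaly must have shape {(S, T)}")
    x = time_covariate(T)                      # (T,)
    m = np.arange(T) % M                       # (T,)
    gamma = np.asarray(latent.gamma, dtype=float)
    gamma_t = gamma[m] if gamma.ndim else np.full(T, float(gamma))
    eta = (
        latent.alpha0 + latent.beta0 * x
        + latent.alpha_state[:, None] + latent.beta_state[:, None] * x
        + latent.alpha_month[m] + latent.beta_month[m] * x
        + latent.zeta[:, m] + latent.psi[:, m] * x
        + latent.nu
        + gamma_t * anomaly
        + latent.epsilon
    )
    return eta


# ---------------------------------------------------------------------------
# Log joint density
# ---------------------------------------------------------------------------

def _gaussian_block_logpdf(x: np.ndarray, R: np.ndarray, rank: int, tau: float,
                           constrained: bool) -> float:
    """Log density of a (possibly intrinsic/constrained) Gaussian block.

    Uses the orthonormal-basis convention for constrained blocks: the block
    lives on the sum-to-zero subspace with precision tau * (A' R A) for an
    orthonormal basis A; its normalising constant uses the product of the
    non-zero eigenvalues of R (the generalised determinant), which equals
    det(A' R A) when R's null space is the constant vector.  For an
    unconstrained singular block (the cyclic-RW1 gamma) the density is
    improper; the flat direction simply contributes nothing.
    """
    x = np.ravel(x)
    quad = float(x @ R @ x)
    ev = np.linalg.eigvalsh(R)
    pos = ev[ev > 1e-9 * max(1.0, ev.max())]
    logdet_plus = float(np.sum(np.log(pos)))
    return 0.5 * rank * np.log(tau) + 0.5 * logdet_plus \
        - 0.5 * rank * np.log(2 * np.pi) - 0.5 * tau * quad


def _log_gamma_hyperprior(log_tau: float, shape: float, rate: float) -> float:
    """Density of the log-gamma hyperprior evaluated at a log precision.

    Equivalent to precision ~ Gamma(shape, rate), with the Jacobian of the
    log transform included.
    """
    return (
        shape * np.log(rate) - gammaln(shape)
        + shape * log_tau - rate * np.exp(log_tau)
    )


def log_joint(
    latent: LatentState,
    spec: ModelSpec,
    deaths: np.ndarray,
    population: np.ndarray,
    anomaly: np.ndarray,
) -> float:
    """Poisson log likelihood plus all log prior terms.

    ``deaths``, ``population`` and ``anomaly`` are (n_states, n_times)
    arrays aligned with ``spec.state_labels`` and the overall time index.
    Constrained blocks must satisfy their sum-to-zero constraints (they do
    by construction everywhere in the package); the density follows the
    constrained-parameterisation convention of :func:`_gaussian_block_logpdf`.
    """
    deaths = np.asarray(deaths, dtype=float)
    population = np.asarray(population, dtype=float)
    if (deaths < 0).any():
        raise ValidationError("negative death counts")
    if (population < 0).any():
        raise ValidationError("negative population")

    eta = linear_predictor_matrix(latent, spec, anomaly)
    mu = np.exp(eta) * population
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(deaths > 0, deaths * np.log(mu), 0.0)
    if np.any((mu == 0) & (deaths > 0)):
        return -np.inf
    loglik = float(np.sum(term - mu - gammaln(deaths + 1.0)))

    lp = loglik
    # fixed effects
    lp += -0.5 * latent.alpha0 ** 2 / spec.intercept_prior_var \
        - 0.5 * np.log(2 * np.pi * spec.intercept_prior_var)
    lp += -0.5 * latent.beta0 ** 2 / spec.slope_prior_var \
        - 0.5 * np.log(2 * np.pi * spec.slope_prior_var)
    if spec.gamma_mode == "common" and spec.components.get("anomaly", True):
        g = float(np.asarray(latent.gamma))
        lp += -0.5 * g ** 2 / spec.slope_prior_var \
            - 0.5 * np.log(2 * np.pi * spec.slope_prior_var)

    for name in spec.active_blocks():
        if name == "gamma" and spec.gamma_mode == "common":
            continue
        tau = np.exp(latent.log_precisions[name])
        R = structure_matrix(spec, name)
        rank = structure_rank(spec, name)
        _, constrained = BLOCK_INFO[name]
        eff_rank = rank - (1 if constrained and rank == block_dim(spec, name) else 0)
        # constrained full-rank blocks (iid) lose one dimension to the constraint
        lp += _gaussian_block_logpdf(
            latent.block(name), R, eff_rank, tau, constrained
        )
        if name not in spec.fixed_log_precisions:
            lp += _log_gamma_hyperprior(
                latent.log_precisions[name], spec.hyper_shape, spec.hyper_rate
            )
    return float(lp)
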