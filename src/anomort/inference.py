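"""Posterior inference for the spatio-temporal Poisson model.

The backend contract is defined by :func:`anomort.model.log_joint`: any
sampler or approximation whose draws target that posterior is conformant.
The implementation here exploits the model's latent-Gaussian structure:

1. Conditional on the latent field, every random-effect precision has an
   exact conjugate Gamma full conditional (Gibbs step).
2. Conditional on the precisions, the latent field posterior is
   log-concave.  A Laplace (Gaussian) approximation is tracked by damped
   Newton steps — the observation-level overdispersion block eliminated
   analytically through a diagonal Schur complement, so each step costs
   one Cholesky of the much smaller structural block — and the field is
   updated by a preconditioned Crank-Nicolson Metropolis move around that
   Gaussian.  The reference Gaussian is a deterministic function of the
   precision history (never of the current latent state), so the
   acceptance ratio is exactly the exact-to-Gaussian density ratio and
   the chain targets the exact posterior however good the approximation.
3. With all precisions fixed there is no chain: draws come from the
   Laplace Gaussian, importance-resampled against the exact joint density
   for low-dimensional instances, which removes the approximation error
   up to Monte-Carlo noise.

Split-chain R-hat on the monitored parameters (fixed effects and anomaly
coefficients) and the latent acceptance rate form the convergence rule.

Draw counts default to 5,000 posterior draws; credible intervals are the
2.5th-97.5th empirical percentiles with the linear-interpolation estimator.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.sparse as sp

from .errors import ConvergenceError, ValidationError
from .model import (
    BLOCK_INFO,
    LatentState,
    ModelSpec,
    block_dim,
    structure_matrix,
    structure_rank,
    time_covariate,
)

__all__ = [
    "PosteriorDraws",
    "fit",
    "fit_arrays",
    "rate_ratio_draws",
    "credible_interval",
    "align_model_arrays",
]

# ---------------------------------------------------------------------------
# Posterior draws container
# ---------------------------------------------------------------------------

@dataclass
class PosteriorDraws:
    """Matrix of posterior draws with named parameter blocks.

    ``draws[name]`` is an (n_draws, dim) array in natural coordinates (the
    sum-to-zero constraints hold exactly in every draw).  ``hyper`` maps
    block name to (n_draws,) arrays of log precisions.  ``meta`` records
    backend, seed and convergence diagnostics.
    """

    draws: dict
    hyper: dict
    meta: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    def gamma(self) -> np.ndarray:
        """Anomaly-coefficient draws, shape (n_draws, 12) or (n_draws, 1)."""
        return self.draws["gamma"]

    def get(self, name: str) -> np.ndarray:
        if name == "alpha_state":
            return self.draws["u_alpha"] + self.draws["v_alpha"]
        if name == "beta_state":
            return self.draws["u_beta"] + self.draws["v_beta"]
        return self.draws[name]

    def to_frame(self) -> pd.DataFrame:
        """Flat DataFrame with one column per scalar parameter."""
        cols = {}
        for name, arr in self.draws.items():
            if arr.ndim == 1:
                arr = arr[:, None]
            for j in range(arr.shape[1]):
                key = name if arr.shape[1] == 1 else f"{name}[{j + 1}]"
                cols[key] = arr[:, j]
        for name, arr in self.hyper.items():
            cols[f"log_prec_{name}"] = arr
        return pd.DataFrame(cols)

def credible_interval(values, level: float = 0.95) -> tuple[float, float]:
    """Equal-tailed empirical credible interval of per-draw values.

    Uses the linear-interpolation percentile estimator; the default level
    0.95 yields the 2.5th and 97.5th percentiles.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValidationError("credible_interval needs at least 2 draws")
    a = (1.0 - level) / 2.0
    lo, hi = np.quantile(values, [a, 1.0 - a], method="linear")
    return float(lo), float(hi)

def rate_ratio_draws(draws: PosteriorDraws, month: int, delta: float = 1.0) -> np.ndarray:
    """Per-draw death-rate ratio for a ``delta`` deg C anomaly in ``month``.

    ``gamma[m]`` is the log rate ratio per 1 deg C, so the ratio is
    ``exp(gamma_m * delta)``.
    """
    if not 1 <= month <= 12:
        raise ValidationError("month must be in 1..12")
    g = draws.gamma()
    col = g[:, month - 1] if g.shape[1] > 1 else g[:, 0]
    return np.exp(col * delta)

# ---------------------------------------------------------------------------
# Data alignment
# ---------------------------------------------------------------------------

def align_model_arrays(
    spec: ModelSpec, data: pd.DataFrame, anomalies: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict]:
    """Pivot stratified counts + anomalies onto the (state, time) grid.

    ``data`` must contain exactly one stratum (one combination of any of
    ``injury_type``, ``sex``, ``age_group`` present) with columns
    ``state, year, month, deaths, population`` covering the full grid of
    ``spec.state_labels`` x months.  ``anomalies`` uses ``unit_id`` for the
    state label.  Returns (deaths, population, anomaly) arrays of shape
    (n_states, n_times) plus grid metadata.
    """
    for col in ("state", "year", "month", "deaths", "population"):
        if col not in data.columns:
            raise ValidationError(f"stratified counts missing column {col!r}")
    strat_cols = [c for c in ("injury_type", "sex", "age_group") if c in data.columns]
    if strat_cols:
        combos = data[strat_cols].drop_duplicates()
        if len(combos) > 1:
            raise ValidationError(
                "fit expects a single stratum per call; found "
                f"{len(combos)} combinations of {strat_cols} "
                "(run per-stratum fits separately)"
            )
    if (data["deaths"] < 0).any():
        raise ValidationError("negative death counts")
    if (data["population"] <= 0).any():
        raise ValidationError("non-positive population")

    year0 = int(data["year"].min())
    data = data.assign(_t=(data["year"] - year0) * 12 + data["month"] - 1)
    n_times = spec.n_times
    if data["_t"].max() >= n_times or data["_t"].min() < 0:
        raise ValidationError("data does not fit the spec's n_times window")

    def _pivot(df, value):
        p = df.pivot_table(index="state" if "state" in df else "unit_id",
                           columns="_t", values=value, aggfunc="sum")
        p = p.reindex(index=spec.state_labels, columns=range(n_times))
        if p.isna().any().any():
            missing = int(p.isna().sum().sum())
            raise ValidationError(
                f"{missing} missing (state, time) cells for {value!r}; the model "
                "requires a complete state x month grid"
            )
        return p.to_numpy(dtype=float)

    deaths = _pivot(data, "deaths")
    population = _pivot(data, "population")
    an = anomalies.rename(columns={"unit_id": "state"})
    an = an.assign(_t=(an["year"] - year0) * 12 + an["month"] - 1)
    an = an[(an["_t"] >= 0) & (an["_t"] < n_times)]
    anomaly = _pivot(an, "anomaly")

    if deaths.sum() == 0:
        raise ValidationError(
            "all-zero death series; aggregate strata or use a coarser unit "
            "before fitting"
        )
    meta = {"year0": year0, "strata": {c: data[c].iloc[0] for c in strat_cols}}
    return deaths, population, anomaly, meta

# ---------------------------------------------------------------------------
# Internal assembly of the reduced-coordinate latent system
# ---------------------------------------------------------------------------

def _constraint_basis(n: int) -> sp.csr_array:
    """Sparse basis of the sum-to-zero subspace: x = A z, A = [I; -1']."""
    rows = np.concatenate([np.arange(n - 1), np.full(n - 1, n - 1)])
    cols = np.concatenate([np.arange(n - 1), np.arange(n - 1)])
    data = np.concatenate([np.ones(n - 1), -np.ones(n - 1)])
    return sp.csr_array((data, (rows, cols)), shape=(n, n - 1))

class _Assembly:
    """Reduced-coordinate design, priors and Laplace machinery for one fit."""

    def __init__(self, spec: ModelSpec, deaths, population, anomaly):
        self.spec = spec
        S, T, M = spec.n_states, spec.n_times, spec.n_months
        self.y = np.asarray(deaths, dtype=float).ravel()          # obs i = s*T + t
        pop = np.asarray(population, dtype=float).ravel()
        self.offset = np.log(pop)
        self.anom = np.asarray(anomaly, dtype=float)
        N = S * T
        self.N = N

        x = time_covariate(T)
        s_idx = np.repeat(np.arange(S), T)
        t_idx = np.tile(np.arange(T), S)
        m_idx = t_idx % M
        xt = x[t_idx]
        ones = np.ones(N)
        a_flat = self.anom.ravel()
        rows = np.arange(N)

        def M_of(cols, data, n):
            return sp.csr_array((data, (rows, cols)), shape=(N, n))

        comp = spec.components
        active = spec.active_blocks()
        # (name, design M, natural dim, structure kind, constrained, hyper?)
        defs = [("alpha0", M_of(np.zeros(N, int), ones, 1), 1, None, False, False),
                ("beta0", M_of(np.zeros(N, int), xt, 1), 1, None, False, False)]
        if comp.get("anomaly", True) and spec.gamma_mode == "common":
            defs.append(("gamma", M_of(np.zeros(N, int), a_flat, 1), 1, None, False, False))
        for name in active:
            if name == "epsilon":
                continue
            n = block_dim(spec, name)
            if name in ("u_alpha", "v_alpha"):
                Mb = M_of(s_idx, ones, n)
            elif name in ("u_beta", "v_beta"):
                Mb = M_of(s_idx, xt, n)
            elif name == "alpha_month":
                Mb = M_of(m_idx, ones, n)
            elif name == "beta_month":
                Mb = M_of(m_idx, xt, n)
            elif name == "zeta":
                Mb = M_of(s_idx * M + m_idx, ones, n)
            elif name == "psi":
                Mb = M_of(s_idx * M + m_idx, xt, n)
            elif name == "nu":
                Mb = M_of(t_idx, ones, n)
            elif name == "gamma":
                Mb = M_of(m_idx, a_flat, n)
            kind, constrained = BLOCK_INFO[name]
            defs.append((name, Mb, n, kind, constrained, True))

        self.blocks = []
        Zcols = []
        p = 0
        for name, Mb, n, kind, constrained, hyper in defs:
            if constrained:
                A = _constraint_basis(n)
                d = n - 1
                Zb = (Mb @ A).tocsr()
            else:
                A = sp.identity(n, format="csr")
                d = n
                Zb = Mb
            if name in ("alpha0",):
                Rz, rank = np.array([[1.0 / spec.intercept_prior_var]]), 0
            elif name in ("beta0",) or (name == "gamma" and spec.gamma_mode == "common"):
                Rz, rank = np.array([[1.0 / spec.slope_prior_var]]), 0
            else:
                R = structure_matrix(spec, name)
                Rz = (A.T @ R @ A) if constrained else R
                Rz = np.asarray(Rz.todense()) if sp.issparse(Rz) else np.asarray(Rz)
                rank = structure_rank(spec, name)
                if constrained and rank == n:       # iid blocks lose one dim
                    rank = n - 1
            self.blocks.append(dict(
                name=name, sl=slice(p, p + d), A=A, Rz=Rz, rank=rank,
                hyper=hyper and name not in spec.fixed_log_precisions,
                fixed_logtau=spec.fixed_log_precisions.get(name),
            ))
            Zcols.append(Zb)
            p += d
        self.p_r = p
        self.Z = sp.hstack(Zcols, format="csr")
        self.ZT = self.Z.T.tocsr()
        # dense design fast path: BLAS beats sparse products only while the
        # normal-equations GEMM (N * p^2 flops) stays small
        self.Zd = self.Z.toarray() if N * p * p <= 2.5e8 else None

        self.eps_active = comp.get("overdispersion", True)
        self.eps_hyper = self.eps_active and "epsilon" not in spec.fixed_log_precisions
        self.eps_fixed_logtau = spec.fixed_log_precisions.get("epsilon")
        self.p_total = self.p_r + (N if self.eps_active else 0)

        self.theta_names = [b["name"] for b in self.blocks if b["hyper"]]
        if self.eps_hyper:
            self.theta_names.append("epsilon")
        self.d_theta = len(self.theta_names)

    # -- theta handling ----------------------------------------------------
    def _block_tau(self, b, theta):
        if b["name"] in ("alpha0", "beta0"):
            return 1.0
        if b["name"] == "gamma" and self.spec.gamma_mode == "common":
            return 1.0
        if b["hyper"]:
            return float(np.exp(theta[self.theta_names.index(b["name"])]))
        return float(np.exp(b["fixed_logtau"]))

    def _tau_eps(self, theta):
        if not self.eps_active:
            return None
        if self.eps_hyper:
            return float(np.exp(theta[self.theta_names.index("epsilon")]))
        return float(np.exp(self.eps_fixed_logtau))

    def _Q_r(self, theta):
        Q = np.zeros((self.p_r, self.p_r))
        for b in self.blocks:
            tau = self._block_tau(b, theta)
            if b["name"] in ("alpha0", "beta0") or (
                b["name"] == "gamma" and self.spec.gamma_mode == "common"
            ):
                Q[b["sl"], b["sl"]] += b["Rz"]      # fixed-variance fixed effects
            else:
                Q[b["sl"], b["sl"]] += tau * b["Rz"]
        return Q

    # -- objective ---------------------------------------------------------
    def _log_prior_theta_terms(self, theta):
        """Sum over blocks of (rank/2) log tau + hyperprior densities."""
        spec = self.spec
        out = 0.0
        for b in self.blocks:
            if b["name"] in ("alpha0", "beta0"):
                continue
            if b["name"] == "gamma" and spec.gamma_mode == "common":
                continue
            tau = self._block_tau(b, theta)
            out += 0.5 * b["rank"] * np.log(tau)
            if b["hyper"]:
                lt = np.log(tau)
                out += spec.hyper_shape * lt - spec.hyper_rate * tau
        if self.eps_active:
            tau = self._tau_eps(theta)
            out += 0.5 * self.N * np.log(tau)
            if self.eps_hyper:
                out += spec.hyper_shape * np.log(tau) - spec.hyper_rate * tau
        return out

    def _Zmul(self, v):
        return self.Zd @ v if self.Zd is not None else self.Z @ v

    def _Ztmul(self, v):
        return self.Zd.T @ v if self.Zd is not None else self.ZT @ v

    def _logpost(self, r, eps, theta, Q_r, tau_eps):
        """Log posterior kernel (constants independent of (r, eps, theta)
        dropped, but all theta-dependent normalisers included)."""
        eta = self.offset + self._Zmul(r) + (eps if eps is not None else 0.0)
        if np.max(eta) > 500:
            return -np.inf, None
        mu = np.exp(eta)
        ll = float(self.y @ (eta - self.offset) - mu.sum())
        quad = float(r @ (Q_r @ r))
        if eps is not None:
            quad += tau_eps * float(eps @ eps)
        return ll - 0.5 * quad + self._log_prior_theta_terms(theta), mu

    # -- Laplace at fixed theta -------------------------------------------
    def laplace(self, theta, start=None, tol=2e-6, max_iter=100):
        """Newton mode + Gaussian approximation at fixed hyperparameters.

        Returns a dict with the mode, Cholesky factor of the structural
        Schur complement, the log Laplace marginal, and scratch quantities
        used for sampling.
        """
        Q_r = self._Q_r(theta)
        tau_eps = self._tau_eps(theta)
        if start is None:
            r = np.zeros(self.p_r)
            # initialise the intercept near the crude log rate
            rate0 = max(self.y.sum(), 1.0) / np.exp(self.offset).sum()
            r[0] = np.log(rate0)
            eps = np.zeros(self.N) if self.eps_active else None
        else:
            r = start[0].copy()
            eps = start[1].copy() if start[1] is not None else None

        f, mu = self._logpost(r, eps, theta, Q_r, tau_eps)
        if not np.isfinite(f):
            raise ValidationError(
                "non-finite log joint at initial point (check population "
                "offsets and anomaly values)"
            )
        L = w_tilde = None
        for _ in range(max_iter):
            w = mu
            if self.eps_active:
                w_tilde = w * tau_eps / (w + tau_eps)
                g_eps = (self.y - mu) - tau_eps * eps
                g_r = self._Ztmul(self.y - mu) - Q_r @ r
                rhs = g_r + self._Ztmul(w * g_eps / (w + tau_eps))
            else:
                w_tilde = w
                g_r = self._Ztmul(self.y - mu) - Q_r @ r
                rhs = g_r
            if self.Zd is not None:
                A = self.Zd * np.sqrt(w_tilde)[:, None]
                Smat = Q_r + A.T @ A
            else:
                Zw = self.Z.multiply(w_tilde[:, None]).tocsr()
                Smat = Q_r + np.asarray((self.ZT @ Zw).todense())
            L = sla.cho_factor(Smat, lower=True, check_finite=False, overwrite_a=True)
            dr = sla.cho_solve(L, rhs, check_finite=False)
            if self.eps_active:
                deps = (g_eps - w * self._Zmul(dr)) / (w + tau_eps)
            else:
                deps = None
            # backtracking line search on the log posterior
            step = 1.0
            g_norm = np.max(np.abs(rhs))
            for _ls in range(30):
                r_new = r + step * dr
                eps_new = eps + step * deps if self.eps_active else None
                f_new, mu_new = self._logpost(r_new, eps_new, theta, Q_r, tau_eps)
                if np.isfinite(f_new) and f_new >= f - 1e-12:
                    break
                step *= 0.5
            r, eps, f, mu = r_new, eps_new, f_new, mu_new
            if g_norm < tol * max(1.0, abs(f)):
                break

        # log det of the full Laplace precision
        logdet = 2.0 * np.sum(np.log(np.diag(L[0])))
        if self.eps_active:
            logdet += float(np.sum(np.log(mu + tau_eps)))
        log_marg = f - 0.5 * logdet + 0.5 * self.p_total * np.log(2 * np.pi)
        return dict(r=r, eps=eps, mu=mu, L=L, w=mu, w_tilde=w_tilde,
                    tau_eps=tau_eps, Q_r=Q_r, f=f, log_marg=log_marg,
                    theta=np.asarray(theta, dtype=float))

    # -- exact Gaussian draws from the approximation -----------------------
    def gaussian_draws(self, lap, n, rng):
        """n exact draws from the Laplace Gaussian N(mode, Q^{-1})."""
        p_r = self.p_r
        xi = rng.standard_normal((n, p_r))
        # marginal precision of the structural block is the Schur complement;
        # trans="T" reads only the lower triangle of the factor
        dr = sla.solve_triangular(
            lap["L"][0], xi.T, lower=True, trans="T", check_finite=False
        ).T
        r = lap["r"][None, :] + dr
        if self.eps_active:
            w, tau_eps = lap["w"], lap["tau_eps"]
            zeta = rng.standard_normal((n, self.N))
            cond_mean = lap["eps"][None, :] - (w * self._Zmul(dr.T).T) / (w + tau_eps)
            eps = cond_mean + zeta / np.sqrt(w + tau_eps)
        else:
            eps = None
        return r, eps

    def log_weights(self, lap, r, eps):
        """Importance log weights of Gaussian draws against the exact joint."""
        theta, Q_r, tau_eps = lap["theta"], lap["Q_r"], lap["tau_eps"]
        n = r.shape[0]
        out = np.empty(n)
        f_mode = lap["f"]
        w = lap["w"]
        for i in range(n):
            e_i = eps[i] if eps is not None else None
            f_i, _ = self._logpost(r[i], e_i, theta, Q_r, tau_eps)
            dr = r[i] - lap["r"]
            qf = float(dr @ (Q_r @ dr))
            zdr = self._Zmul(dr)
            if eps is not None:
                de = eps[i] - lap["eps"]
                qf += float(w @ (zdr + de) ** 2) + tau_eps * float(de @ de)
            else:
                qf += float(w @ zdr ** 2)
            out[i] = f_i - f_mode + 0.5 * qf
        return out

    # -- mapping back to natural coordinates -------------------------------
    def natural_draws(self, r_draws):
        out = {}
        for b in self.blocks:
            z = r_draws[:, b["sl"]]
            out[b["name"]] = (b["A"] @ z.T).T
        return out

# ---------------------------------------------------------------------------
# Markov chain Monte Carlo (Metropolis-within-Gibbs)
# ---------------------------------------------------------------------------

def _split_rhat(x: np.ndarray) -> float:
    """Split-chain potential scale reduction factor of one scalar series."""
    n = len(x) // 2 * 2
    if n < 4:
        return np.nan
    a = x[:n].reshape(2, n // 2)
    W = float(a.var(axis=1, ddof=1).mean())
    if W <= 1e-300:
        return 1.0
    B = (n // 2) * float(a.mean(axis=1).var(ddof=1))
    var_plus = (n // 2 - 1) / (n // 2) * W + B / (n // 2)
    return float(np.sqrt(var_plus / W))

# ---------------------------------------------------------------------------
# Public fitting API
# ---------------------------------------------------------------------------

def fit_arrays(
    spec: ModelSpec,
    deaths: np.ndarray,
    population: np.ndarray,
    anomaly: np.ndarray,
    *,
    seed: int,
    n_draws: int = 5000,
    warmup: int = 500,
    samples: int = 2500,
    target_accept: float = 0.35,
    refine: str | bool = "auto",
    refine_max_dim: int = 40,
    rhat_max: float = 1.01,
    min_accept: float = 0.05,
    on_nonconvergence: str = "raise",
    store_epsilon: bool = True,
) -> PosteriorDraws:
    """Fit the model to (n_states, n_times) arrays and return posterior draws.

    The sampler is a Metropolis-within-Gibbs scheme targeting the exact
    posterior of :func:`anomort.model.log_joint`:

    * every random-effect precision is redrawn from its exact conjugate
      Gamma full conditional given the latent field;
    * the whole latent field is updated by a preconditioned Crank-Nicolson
      Metropolis step whose Gaussian reference is the Laplace approximation
      at the current precisions, so the acceptance ratio involves only the
      exact-to-Gaussian density ratio.  The retention coefficient is
      adapted during warmup towards ``target_accept`` and frozen afterwards.

    ``warmup`` iterations are discarded; ``samples`` retained iterations are
    thinned (or recycled) to exactly ``n_draws`` draws (default 5,000).
    Convergence rule: split-chain R-hat below ``rhat_max`` on the monitored
    parameters (the fixed effects and every anomaly coefficient) and a mean
    latent acceptance probability of at least ``min_accept``; failure
    raises :class:`ConvergenceError` unless ``on_nonconvergence="warn"``
    (hyperparameter R-hats are reported, not gated, since weakly identified
    precisions mix slowly without affecting the monitored posteriors).

    With every precision fixed (``spec.fixed_log_precisions``) there is no
    Gibbs loop: draws come from the Laplace Gaussian at the fixed
    precisions and — when the latent dimension is at most
    ``refine_max_dim`` and ``refine`` is "auto" or True — are importance-
    resampled against the exact joint density, which removes the
    approximation error up to Monte-Carlo noise.
    """
    t0 = time.time()
    rng = np.random.default_rng(seed)
    deaths = np.asarray(deaths, dtype=float)
    if deaths.sum() == 0:
        raise ValidationError(
            "all-zero death series; aggregate strata before fitting"
        )
    asm = _Assembly(spec, deaths, population, anomaly)
    do_refine = refine is True or (refine == "auto" and asm.p_total <= refine_max_dim)
    diagnostics = {"backend": "gibbs_pcn", "seed": int(seed),
                   "theta_names": list(asm.theta_names)}

    if asm.d_theta == 0:
        # fixed hyperparameters: a single latent-Gaussian conditional
        lap = asm.laplace(np.empty(0))
        r_all, eps_all = asm.gaussian_draws(lap, n_draws, rng)
        if do_refine:
            logw = asm.log_weights(lap, r_all, eps_all)
            w = np.exp(logw - logw.max())
            w /= w.sum()
            idx = rng.choice(n_draws, size=n_draws, replace=True, p=w)
            r_all = r_all[idx]
            if eps_all is not None:
                eps_all = eps_all[idx]
            diagnostics["is_ess"] = float(1.0 / np.sum(w ** 2))
        diagnostics.update(refined=bool(do_refine), x_accept=None, rhat=None)
        hyper_all = np.empty((n_draws, 0))
    else:
        theta = np.full(asm.d_theta, np.log(100.0))
        if "epsilon" in asm.theta_names:
            theta[asm.theta_names.index("epsilon")] = np.log(400.0)
        lap = asm.laplace(theta)
        if not np.isfinite(lap["f"]):
            raise ValidationError("non-finite log joint at initialisation")
        r = lap["r"].copy()
        eps = lap["eps"].copy() if lap["eps"] is not None else None
        # reference-mode recursion: the pCN reference Gaussian is a
        # deterministic function of the precision history (a couple of
        # Newton steps from the previous reference), never of the current
        # latent state, which keeps the Metropolis ratio exact
        ref = (r.copy(), None if eps is None else eps.copy())
        shape0, rate0 = spec.hyper_shape, spec.hyper_rate
        hyper_blocks = [b for b in asm.blocks if b["hyper"]]
        th_index = {name: j for j, name in enumerate(asm.theta_names)}

        keep_r = np.empty((samples, asm.p_r))
        keep_eps = np.empty((samples, asm.N)) if asm.eps_active else None
        keep_th = np.empty((samples, asm.d_theta))
        a_raw = 0.0               # logit of the pCN retention coefficient
        acc_sum = 0.0
        for it in range(warmup + samples):
            # exact conjugate Gamma updates of the precisions
            for b in hyper_blocks:
                z = r[b["sl"]]
                quad = float(z @ (b["Rz"] @ z))
                tau = rng.gamma(shape0 + 0.5 * b["rank"],
                                1.0 / (rate0 + 0.5 * quad))
                theta[th_index[b["name"]]] = np.log(tau)
            if asm.eps_hyper:
                tau = rng.gamma(shape0 + 0.5 * asm.N,
                                1.0 / (rate0 + 0.5 * float(eps @ eps)))
                theta[th_index["epsilon"]] = np.log(tau)

            # pCN Metropolis update of the latent field around the Laplace
            # Gaussian at the current precisions
            lap = asm.laplace(theta, start=ref, max_iter=2)
            ref = (lap["r"], lap["eps"])
            alpha = 1.0 / (1.0 + np.exp(-a_raw))
            prop_r, prop_eps = asm.gaussian_draws(lap, 1, rng)
            beta = np.sqrt(1.0 - alpha ** 2)
            r_new = lap["r"] + alpha * (r - lap["r"]) + beta * (prop_r[0] - lap["r"])
            if asm.eps_active:
                eps_new = (lap["eps"] + alpha * (eps - lap["eps"])
                           + beta * (prop_eps[0] - lap["eps"]))
            else:
                eps_new = None
            lw_cur = asm.log_weights(lap, r[None, :],
                                     None if eps is None else eps[None, :])[0]
            lw_new = asm.log_weights(lap, r_new[None, :],
                                     None if eps_new is None else eps_new[None, :])[0]
            acc_p = float(np.exp(min(0.0, lw_new - lw_cur)))
            if rng.uniform() < acc_p:
                r, eps = r_new, eps_new
            if it < warmup:
                a_raw += (it + 10.0) ** -0.6 * (target_accept - acc_p)
            else:
                k = it - warmup
                keep_r[k] = r
                if keep_eps is not None:
                    keep_eps[k] = eps
                keep_th[k] = theta
                acc_sum += acc_p

        x_accept = acc_sum / samples
        # split-Rhat on the monitored parameters
        monitored = {"alpha0": keep_r[:, 0], "beta0": keep_r[:, 1]}
        for b in asm.blocks:
            if b["name"] == "gamma":
                g = keep_r[:, b["sl"]]
                for j in range(g.shape[1]):
                    monitored[f"gamma[{j + 1}]"] = g[:, j]
        rhats = {k: _split_rhat(v) for k, v in monitored.items()}
        rhat = float(np.nanmax(list(rhats.values())))
        rhat_hyper = float(np.nanmax([_split_rhat(keep_th[:, j])
                                      for j in range(asm.d_theta)]))
        diagnostics.update(
            x_accept=float(x_accept), pcn_alpha=float(1 / (1 + np.exp(-a_raw))),
            rhat=rhat, rhat_hyper=rhat_hyper, refined=False,
        )
        if rhat > rhat_max or x_accept < min_accept:
            msg = (f"chain failed convergence rule: split-Rhat={rhat:.4f} "
                   f"(max {rhat_max}) on monitored parameters, latent "
                   f"acceptance={x_accept:.3f} (min {min_accept})")
            if on_nonconvergence == "raise":
                raise ConvergenceError(msg)
            import warnings
            warnings.warn(msg, stacklevel=2)

        # thin (or recycle) the retained iterations to exactly n_draws
        if samples >= n_draws:
            sel = np.linspace(0, samples - 1, n_draws).astype(int)
        else:
            sel = np.resize(np.arange(samples), n_draws)
        r_all = keep_r[sel]
        eps_all = keep_eps[sel] if keep_eps is not None else None
        hyper_all = keep_th[sel]

    nat = asm.natural_draws(r_all)
    draws = {"alpha0": nat["alpha0"], "beta0": nat["beta0"]}
    for b in asm.blocks:
        if b["name"] not in ("alpha0", "beta0"):
            draws[b["name"]] = nat[b["name"]]
    if asm.eps_active and store_epsilon:
        draws["epsilon"] = eps_all
    hyper = {name: hyper_all[:, j] for j, name in enumerate(asm.theta_names)}
    diagnostics["runtime_s"] = round(time.time() - t0, 3)
    diagnostics["n_draws"] = n_draws
    return PosteriorDraws(draws=draws, hyper=hyper, meta=diagnostics)

def fit(
    spec: ModelSpec,
    data: pd.DataFrame,
    anomalies: pd.DataFrame,
    *,
    seed: int,
    **options,
) -> PosteriorDraws:
    """Fit the model to one stratum of stratified counts.

    ``data`` is a StratifiedCounts frame (``state, year, month, deaths,
    population`` plus optional stratum columns, a single stratum per call);
    ``anomalies`` an AnomalySeries frame at state level.  See
    :func:`fit_arrays` for sampler options.
    """
    deaths, population, anomaly, meta = align_model_arrays(spec, data, anomalies)
    out = fit_arrays(spec, deaths, population, anomaly, seed=seed, **options)
    out.meta["stratum"] = meta["strata"]
    out.meta["year0"] = meta["year0"]
    return out
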