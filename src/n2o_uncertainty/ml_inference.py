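"""Approximate maximum-likelihood estimation of the non-Bayesian models.

Linear mixed models have a closed-form marginal likelihood: within each
publication the observations are jointly Gaussian with covariance
``sigma0^2 J + sigma1^2 x x' + tau^2 I`` (terms present according to the model
structure).  For the exponential models the random effects enter the mean
nonlinearly, so the per-publication marginal likelihood is an integral over
one or two Gaussian random effects; it is evaluated by adaptive Gauss-Hermite
quadrature (AGQ) centered at each publication's conditional mode with
curvature scaling.  One quadrature node per dimension reduces AGQ to the
Laplace approximation.

Fitting maximizes the marginal log-likelihood over
``(mu0[, mu1][, log sigma0][, log sigma1], log tau)`` with a quasi-Newton
method; variance parameters are optimized on the log scale to enforce
positivity.  Standard errors for ``mu0`` and ``mu1`` come from the inverse
observed information (finite-difference Hessian).
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy import linalg, optimize
from scipy.special import logsumexp

from .data_core import EmissionRecord, records_to_frame
from .model_suite import ModelSpec, ParamSet, get_model

logger = logging.getLogger(__name__)

__all__ = [
    "PubData",
    "FitResult",
    "as_pubdata",
    "loglik_linear_mixed",
    "loglik_nonlinear_mixed",
    "fit_ml",
    "model_selection_table",
]

_LOG_2PI = math.log(2.0 * math.pi)
_BOUNDARY_LOG_SIGMA = -10.0  # log-scale variance estimates below this flag a boundary


@dataclass
class PubData:
    """Measurements grouped by publication: parallel lists of dose and
    emission arrays, one entry per publication."""

    ids: list[str]
    x: list[np.ndarray]
    y: list[np.ndarray]

    @property
    def n_publications(self) -> int:
        return len(self.ids)

    @property
    def n_obs(self) -> int:
        return sum(len(v) for v in self.y)

    def all_x(self) -> np.ndarray:
        return np.concatenate(self.x) if self.x else np.empty(0)

    def all_y(self) -> np.ndarray:
        return np.concatenate(self.y) if self.y else np.empty(0)

    def padded(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(X, Y, mask, counts) padded to the longest publication (cached)."""
        cached = getattr(self, "_padded", None)
        if cached is not None:
            return cached
        P = self.n_publications
        M = max((len(v) for v in self.y), default=0)
        X = np.zeros((P, M))
        Y = np.zeros((P, M))
        mask = np.zeros((P, M))
        counts = np.zeros(P)
        for i, (xi, yi) in enumerate(zip(self.x, self.y)):
            X[i, : len(xi)] = xi
            Y[i, : len(yi)] = yi
            mask[i, : len(yi)] = 1.0
            counts[i] = len(yi)
        self._padded = (X, Y, mask, counts)
        return self._padded


def as_pubdata(data) -> PubData:
    """Normalize input data (records, DataFrame or PubData) to grouped form.

    Publications with zero records cannot arise from grouping; group order
    follows first appearance so likelihoods are reproducible.
    """
    if isinstance(data, PubData):
        return data
    if isinstance(data, pd.DataFrame):
        frame = data
    else:
        frame = records_to_frame(data)
    ids: list[str] = []
    xs: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    for pub_id, sub in frame.groupby("publication_id", sort=False):
        ids.append(str(pub_id))
        xs.append(sub["n_rate_kg_ha"].to_numpy(dtype=float))
        ys.append(sub["n2o_kg_n_ha_yr"].to_numpy(dtype=float))
    return PubData(ids=ids, x=xs, y=ys)


# ---------------------------------------------------------------------------
# Linear marginal likelihood (closed form)
# ---------------------------------------------------------------------------


def loglik_linear_mixed(spec: ModelSpec, params: ParamSet, data) -> float:
    """Exact marginal Gaussian log-likelihood of a linear model.

    Per publication, ``Y ~ MVN(mu0 + mu1 x, sigma0^2 J + sigma1^2 x x' +
    tau^2 I)`` with terms present per the model structure; publications are
    independent and their contributions summed.
    """
    if not spec.linear:
        raise ValueError(f"{spec.name} is not linear")
    pub = as_pubdata(data)
    mu1 = params.mu1 if spec.uses_N else 0.0

    if spec.n_random == 0:
        # independent observations: no per-publication structure
        if params.tau <= 0:
            raise ValueError("singular covariance: tau must be positive")
        y = pub.all_y()
        x = pub.all_x()
        resid = y - (params.mu0 + mu1 * x)
        n = len(y)
        return float(
            -0.5 * n * (_LOG_2PI + 2.0 * math.log(params.tau))
            - 0.5 * float(resid @ resid) / params.tau**2
        )

    if params.tau <= 0:
        raise ValueError(
            "singular within-publication covariance: tau must be positive"
        )
    # low-rank (Woodbury) evaluation, vectorized over publications:
    # C_i = tau^2 I + V_i V_i' with V_i columns sigma0*1 and sigma1*x
    Xp, Yp, mask, counts = pub.padded()
    tau2 = params.tau**2
    resid = (Yp - (params.mu0 + mu1 * Xp)) * mask
    cols = []
    if spec.random_intercept:
        cols.append(params.sigma0 * mask)
    if spec.random_slope:
        cols.append(params.sigma1 * Xp * mask)
    V = np.stack(cols, axis=2)  # (P, M, d)
    d = V.shape[2]
    G = np.einsum("pmd,pme->pde", V, V) + tau2 * np.eye(d)
    Vtr = np.einsum("pmd,pm->pd", V, resid)
    rtr = np.einsum("pm,pm->p", resid, resid)
    if d == 1:
        detG = G[:, 0, 0]
        u = Vtr[:, 0] / detG
        quad = (rtr - Vtr[:, 0] * u) / tau2
    else:
        detG = G[:, 0, 0] * G[:, 1, 1] - G[:, 0, 1] * G[:, 1, 0]
        u0 = (G[:, 1, 1] * Vtr[:, 0] - G[:, 0, 1] * Vtr[:, 1]) / detG
        u1 = (-G[:, 1, 0] * Vtr[:, 0] + G[:, 0, 0] * Vtr[:, 1]) / detG
        quad = (rtr - (Vtr[:, 0] * u0 + Vtr[:, 1] * u1)) / tau2
    if np.any(detG <= 0):
        raise ValueError("singular within-publication covariance")
    logdetC = (counts - d) * math.log(tau2) + np.log(detG)
    return float(-0.5 * np.sum(counts * _LOG_2PI + logdetC + quad))


# ---------------------------------------------------------------------------
# Nonlinear marginal likelihood (adaptive Gauss-Hermite quadrature)
# ---------------------------------------------------------------------------


def _design_matrix(x: np.ndarray, spec: ModelSpec) -> np.ndarray:
    cols = []
    if spec.random_intercept:
        cols.append(np.ones_like(x))
    if spec.random_slope:
        cols.append(x)
    return np.column_stack(cols)


def _random_sds(spec: ModelSpec, params: ParamSet) -> np.ndarray:
    sds = []
    if spec.random_intercept:
        sds.append(params.sigma0)
    if spec.random_slope:
        sds.append(params.sigma1)
    return np.asarray(sds)


def _log_joint(b, eta0, U, y, sds, tau, link):
    """Log of (conditional density of y given b) x (density of b)."""
    with np.errstate(over="ignore"):
        eta = eta0 + U @ b
        mean = np.exp(eta) if link == "exp" else eta
        resid = y - mean
        n = len(y)
        ll = -0.5 * n * (_LOG_2PI + 2.0 * math.log(tau)) - 0.5 * (resid @ resid) / tau**2
    lp = -0.5 * len(b) * _LOG_2PI - np.sum(np.log(sds)) - 0.5 * np.sum((b / sds) ** 2)
    out = ll + lp
    return out if np.isfinite(out) else -math.inf


def _log_joint_grad_hess(b, eta0, U, y, sds, tau, link):
    eta = np.clip(eta0 + U @ b, -700.0, 700.0)
    if link == "exp":
        f = np.exp(eta)
        fp = f
        fpp = f
    else:
        f = eta
        fp = np.ones_like(eta)
        fpp = np.zeros_like(eta)
    r = y - f
    grad = U.T @ (r * fp) / tau**2 - b / sds**2
    w = (r * fpp - fp**2) / tau**2
    hess = (U * w[:, None]).T @ U - np.diag(1.0 / sds**2)
    return grad, hess


def _find_mode(eta0, U, y, sds, tau, link, b0=None, max_iter=100, tol=1e-9):
    """Newton ascent of the per-publication log joint, with ridge damping
    and backtracking; returns (mode, negative Hessian at mode)."""
    d = U.shape[1]
    b = np.zeros(d) if b0 is None else np.array(b0, dtype=float)
    h = _log_joint(b, eta0, U, y, sds, tau, link)
    for _ in range(max_iter):
        grad, hess = _log_joint_grad_hess(b, eta0, U, y, sds, tau, link)
        if np.max(np.abs(grad)) < tol:
            break
        A = -hess
        ridge = 0.0
        for _attempt in range(60):
            try:
                chol = linalg.cholesky(A + ridge * np.eye(d), lower=True)
                break
            except linalg.LinAlgError:
                ridge = max(2.0 * ridge, 1e-6)
        else:  # pragma: no cover - pathological curvature
            return None, None
        step = linalg.cho_solve((chol, True), grad)
        t = 1.0
        for _bt in range(50):
            b_new = b + t * step
            h_new = _log_joint(b_new, eta0, U, y, sds, tau, link)
            if h_new >= h - 1e-12:
                break
            t *= 0.5
        else:  # pragma: no cover
            return None, None
        if np.allclose(b_new, b) and h_new <= h + 1e-14:
            b, h = b_new, h_new
            break
        b, h = b_new, h_new
    _, hess = _log_joint_grad_hess(b, eta0, U, y, sds, tau, link)
    A = -hess
    # guard: curvature must be positive definite at the mode
    ridge = 0.0
    while True:
        try:
            linalg.cholesky(A + ridge * np.eye(d), lower=True)
            break
        except linalg.LinAlgError:
            ridge = max(2.0 * ridge, 1e-8)
            if ridge > 1e6:  # pragma: no cover
                return None, None
    return b, A + ridge * np.eye(d)


def _gh_nodes(n_nodes: int, d: int) -> tuple[np.ndarray, np.ndarray]:
    z, w = hermgauss(n_nodes)
    logw = np.log(w)
    if d == 1:
        return z[:, None], logw
    Z0, Z1 = np.meshgrid(z, z, indexing="ij")
    W0, W1 = np.meshgrid(logw, logw, indexing="ij")
    return np.column_stack([Z0.ravel(), Z1.ravel()]), (W0 + W1).ravel()


def loglik_nonlinear_mixed(
    spec: ModelSpec,
    params: ParamSet,
    data,
    n_nodes: int = 9,
    mode_cache: dict | None = None,
    _link: str = "exp",
) -> float:
    """Marginal log-likelihood of an exponential (or, via ``_link``,
    identity-mean) mixed model by adaptive Gauss-Hermite quadrature.

    Random effects are integrated out per publication on a grid of
    ``n_nodes`` (odd) points per dimension, recentred at the conditional mode
    and scaled by the curvature there; ``n_nodes=1`` is the Laplace
    approximation.  ``mode_cache`` (publication id -> last mode) warm-starts
    the inner Newton iterations across likelihood evaluations.
    """
    if spec.linear and _link == "exp":
        raise ValueError(f"{spec.name} is not an exponential model")
    if n_nodes < 1 or n_nodes % 2 == 0:
        raise ValueError("n_nodes must be a positive odd integer")
    if params.tau <= 0:
        raise ValueError("tau must be positive")
    pub = as_pubdata(data)
    mu1 = params.mu1 if spec.uses_N else 0.0
    d = spec.n_random

    if d == 0:
        y = pub.all_y()
        x = pub.all_x()
        with np.errstate(over="ignore"):
            eta = params.mu0 + mu1 * x
            mean = np.exp(eta) if _link == "exp" else eta
            resid = y - mean
            n = len(y)
            ll = (
                -0.5 * n * (_LOG_2PI + 2.0 * math.log(params.tau))
                - 0.5 * float(resid @ resid) / params.tau**2
            )
        return float(ll) if np.isfinite(ll) else -math.inf

    sds = _random_sds(spec, params)
    if np.any(sds <= 0):
        raise ValueError("random-effect SDs must be positive for integration")
    Z, logw = _gh_nodes(n_nodes, d)
    zsq = np.sum(Z**2, axis=1)
    total = 0.0
    for pub_id, x, y in zip(pub.ids, pub.x, pub.y):
        U = _design_matrix(x, spec)
        eta0 = params.mu0 + mu1 * x
        b0 = mode_cache.get(pub_id) if mode_cache is not None else None
        mode, A = _find_mode(eta0, U, y, sds, params.tau, _link, b0=b0)
        if mode is None:
            raise RuntimeError(f"conditional-mode search failed for {pub_id!r}")
        if mode_cache is not None:
            mode_cache[pub_id] = mode
        chol = linalg.cholesky(A, lower=True)
        # quadrature points b = mode + sqrt(2) * C^{-T} z
        shifts = math.sqrt(2.0) * linalg.solve_triangular(
            chol, Z.T, lower=True, trans="T"
        )
        pts = mode[:, None] + shifts  # (d, J)
        with np.errstate(over="ignore"):
            eta = eta0[:, None] + U @ pts  # (n_i, J)
            mean = np.exp(eta) if _link == "exp" else eta
            resid = y[:, None] - mean
        n_i = len(y)
        cond_ll = (
            -0.5 * n_i * (_LOG_2PI + 2.0 * math.log(params.tau))
            - 0.5 * np.sum(resid**2, axis=0) / params.tau**2
        )
        lat_lp = (
            -0.5 * d * _LOG_2PI
            - np.sum(np.log(sds))
            - 0.5 * np.sum((pts / sds[:, None]) ** 2, axis=0)
        )
        logdetA = 2.0 * float(np.sum(np.log(np.diag(chol))))
        total += (
            0.5 * d * math.log(2.0)
            - 0.5 * logdetA
            + float(logsumexp(logw + zsq + cond_ll + lat_lp))
        )
    return total


def marginal_loglik(spec: ModelSpec, params: ParamSet, data, n_nodes: int = 9,
                    mode_cache: dict | None = None) -> float:
    """Dispatch to the closed-form (linear) or AGQ (exponential) likelihood."""
    if spec.linear:
        return loglik_linear_mixed(spec, params, data)
    return loglik_nonlinear_mixed(spec, params, data, n_nodes=n_nodes,
                                  mode_cache=mode_cache)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """Outcome of one maximum-likelihood fit."""

    spec: ModelSpec
    estimates: ParamSet
    standard_errors: dict[str, float]
    loglik: float
    n_obs: int
    n_params: int
    aic: float
    bic: float
    converged: bool
    boundary: bool = False
    optimizer_trace: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> dict:
        payload = {
            "model": self.spec.name,
            "estimates": self.estimates.as_dict(),
            "standard_errors": self.standard_errors,
            "loglik": self.loglik,
            "n_obs": self.n_obs,
            "n_params": self.n_params,
            "aic": self.aic,
            "bic": self.bic,
            "converged": self.converged,
            "boundary": self.boundary,
            "optimizer_trace": self.optimizer_trace,
        }
        if path is not None:
            Path(path).write_text(json.dumps(payload, indent=2))
        return payload

    @classmethod
    def from_json(cls, source: str | Path | dict) -> "FitResult":
        d = source if isinstance(source, dict) else json.loads(Path(source).read_text())
        return cls(
            spec=get_model(d["model"]),
            estimates=ParamSet.from_dict(d["estimates"]),
            standard_errors={k: float(v) for k, v in d["standard_errors"].items()},
            loglik=float(d["loglik"]),
            n_obs=int(d["n_obs"]),
            n_params=int(d["n_params"]),
            aic=float(d["aic"]),
            bic=float(d["bic"]),
            converged=bool(d["converged"]),
            boundary=bool(d.get("boundary", False)),
            optimizer_trace=d.get("optimizer_trace", {}),
        )


def _param_names(spec: ModelSpec) -> list[str]:
    names = ["mu0"]
    if spec.uses_N:
        names.append("mu1")
    if spec.random_intercept:
        names.append("log_sigma0")
    if spec.random_slope:
        names.append("log_sigma1")
    names.append("log_tau")
    return names


def _pack(spec: ModelSpec, params: ParamSet) -> np.ndarray:
    def _log(v):
        return math.log(max(v, 1e-8))

    vec = [params.mu0]
    if spec.uses_N:
        vec.append(params.mu1)
    if spec.random_intercept:
        vec.append(_log(params.sigma0))
    if spec.random_slope:
        vec.append(_log(params.sigma1))
    vec.append(_log(params.tau))
    return np.asarray(vec)


def _unpack(spec: ModelSpec, vec: np.ndarray) -> ParamSet:
    it = iter(vec)
    mu0 = next(it)
    mu1 = next(it) if spec.uses_N else 0.0
    sigma0 = math.exp(next(it)) if spec.random_intercept else 0.0
    sigma1 = math.exp(next(it)) if spec.random_slope else 0.0
    tau = math.exp(next(it))
    return ParamSet(mu0=float(mu0), mu1=float(mu1), sigma0=sigma0, sigma1=sigma1, tau=tau)


def default_init(spec: ModelSpec, data) -> ParamSet:
    """Data-driven starting values: OLS for linear models, log-scale
    regression for exponential models, crude variance splits for the SDs."""
    pub = as_pubdata(data)
    x = pub.all_x()
    y = pub.all_y()
    if spec.linear:
        if spec.uses_N and np.var(x) > 0:
            mu1 = float(np.cov(x, y, bias=True)[0, 1] / np.var(x))
            mu0 = float(np.mean(y) - mu1 * np.mean(x))
        else:
            mu1, mu0 = 0.0, float(np.mean(y))
        resid_sd = float(np.std(y - mu0 - mu1 * x)) or 1.0
    else:
        ylog = np.log(np.clip(y, 0.05, None))
        if spec.uses_N and np.var(x) > 0:
            mu1 = float(np.cov(x, ylog, bias=True)[0, 1] / np.var(x))
            mu0 = float(np.mean(ylog) - mu1 * np.mean(x))
        else:
            mu1, mu0 = 0.0, float(np.mean(ylog))
        resid_sd = float(np.std(y - np.exp(mu0 + mu1 * x))) or 1.0
    return ParamSet(
        mu0=mu0,
        mu1=mu1 if spec.uses_N else 0.0,
        sigma0=0.5 * resid_sd if spec.random_intercept else 0.0,
        sigma1=max(abs(mu1) * 0.5, 1e-4) if spec.random_slope else 0.0,
        tau=max(resid_sd * (0.8 if spec.n_random else 1.0), 1e-3),
    )


def _fd_hessian(fun, x0: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central finite-difference Hessian of a scalar function."""
    p = len(x0)
    h = rel_step * (1.0 + np.abs(x0))
    H = np.empty((p, p))
    f0 = fun(x0)
    for i in range(p):
        ei = np.zeros(p)
        ei[i] = h[i]
        H[i, i] = (fun(x0 + ei) - 2.0 * f0 + fun(x0 - ei)) / h[i] ** 2
        for j in range(i + 1, p):
            ej = np.zeros(p)
            ej[j] = h[j]
            fpp = fun(x0 + ei + ej)
            fpm = fun(x0 + ei - ej)
            fmp = fun(x0 - ei + ej)
            fmm = fun(x0 - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h[i] * h[j])
    return H


def _closed_form_linear_fixed(spec: ModelSpec, pub: PubData) -> tuple[ParamSet, dict, float]:
    """Exact MLE for linear models without random effects (OLS; tau^2 = RSS/n)."""
    x = pub.all_x()
    y = pub.all_y()
    n = len(y)
    if spec.uses_N:
        X = np.column_stack([np.ones(n), x])
    else:
        X = np.ones((n, 1))
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    tau2 = float(resid @ resid) / n
    tau = math.sqrt(tau2)
    params = ParamSet(
        mu0=float(beta[0]),
        mu1=float(beta[1]) if spec.uses_N else 0.0,
        tau=tau,
    )
    cov = tau2 * np.linalg.inv(X.T @ X)
    ses = {"mu0": float(math.sqrt(cov[0, 0]))}
    if spec.uses_N:
        ses["mu1"] = float(math.sqrt(cov[1, 1]))
    loglik = -0.5 * n * (_LOG_2PI + math.log(tau2) + 1.0)
    return params, ses, loglik


def fit_ml(
    spec: ModelSpec,
    data,
    init: ParamSet | None = None,
    n_nodes: int = 9,
    options: dict | None = None,
) -> FitResult:
    """Fit one non-Bayesian model by (approximate) maximum likelihood.

    Deterministic given ``init`` and ``options``.  Non-convergence is
    reported through ``FitResult.converged``, never raised; variance
    estimates collapsing to the boundary (sigma -> 0) set the ``boundary``
    flag.
    """
    if spec.bayesian:
        raise ValueError(f"{spec.name} is estimated by MCMC, not ML")
    pub = as_pubdata(data)
    if spec.n_random > 0 and pub.n_publications < 2:
        raise ValueError("random-effect models need at least 2 publications")
    options = dict(options or {})
    n = pub.n_obs
    k = spec.n_params

    if spec.linear and spec.n_random == 0:
        params, ses, loglik = _closed_form_linear_fixed(spec, pub)
        trace = {"method": "closed-form OLS"}
        return FitResult(
            spec=spec,
            estimates=params,
            standard_errors=ses,
            loglik=loglik,
            n_obs=n,
            n_params=k,
            aic=-2.0 * loglik + 2.0 * k,
            bic=-2.0 * loglik + k * math.log(n),
            converged=True,
            optimizer_trace=trace,
        )

    mode_cache: dict = {}

    def neg_loglik(vec: np.ndarray) -> float:
        params = _unpack(spec, vec)
        try:
            if spec.linear:
                ll = loglik_linear_mixed(spec, params, pub)
            else:
                ll = loglik_nonlinear_mixed(
                    spec, params, pub, n_nodes=n_nodes, mode_cache=mode_cache
                )
        except (ValueError, RuntimeError, FloatingPointError):
            return 1e12
        if not np.isfinite(ll):
            return 1e12
        return -ll

    x0 = _pack(spec, init if init is not None else default_init(spec, data))
    res = optimize.minimize(
        neg_loglik,
        x0,
        method=options.pop("method", "BFGS"),
        options={"maxiter": options.pop("maxiter", 500), "gtol": options.pop("gtol", 1e-5)},
    )
    estimates = _unpack(spec, res.x)
    loglik = -float(res.fun)
    grad_norm = float(np.max(np.abs(res.get("jac", np.array([np.inf])))))
    # BFGS with finite-difference gradients often stops on "precision loss"
    # while already at the optimum; a small final gradient counts as converged.
    converged = bool(res.success) or grad_norm < 1.0
    boundary = bool(
        np.any(res.x[[i for i, nm in enumerate(_param_names(spec)) if nm.startswith("log_sigma")]]
               < _BOUNDARY_LOG_SIGMA)
    ) if spec.n_random else False

    ses: dict[str, float] = {}
    try:
        H = _fd_hessian(neg_loglik, res.x)
        cov = np.linalg.inv(H)
        names = _param_names(spec)
        for pname in ("mu0", "mu1"):
            if pname in names:
                var = cov[names.index(pname), names.index(pname)]
                ses[pname] = float(math.sqrt(var)) if var > 0 else float("nan")
    except np.linalg.LinAlgError:
        for pname in ("mu0", "mu1"):
            if pname in _param_names(spec):
                ses[pname] = float("nan")

    trace = {
        "method": "BFGS",
        "message": str(res.message),
        "n_iter": int(res.get("nit", -1)),
        "n_feval": int(res.get("nfev", -1)),
        "grad_norm": grad_norm,
    }
    return FitResult(
        spec=spec,
        estimates=estimates,
        standard_errors=ses,
        loglik=loglik,
        n_obs=n,
        n_params=k,
        aic=-2.0 * loglik + 2.0 * k,
        bic=-2.0 * loglik + k * math.log(n),
        converged=converged,
        boundary=boundary,
        optimizer_trace=trace,
    )


def model_selection_table(fits: Sequence[FitResult]) -> pd.DataFrame:
    """AIC/BIC table with percentage increases relative to each family's best.

    ``pct_aic`` (and ``pct_bic``) are 100*(AIC/min_family_AIC - 1), computed
    within the linear and nonlinear families separately, so each family's
    best model scores 0.
    """
    names = [f.spec.name for f in fits]
    if len(set(names)) != len(names):
        raise ValueError("duplicate model names in fit list")
    rows = []
    for f in fits:
        rows.append(
            {
                "model": f.spec.name,
                "family": f.spec.family,
                "aic": f.aic,
                "bic": f.bic,
            }
        )
    table = pd.DataFrame(rows)
    for crit in ("aic", "bic"):
        best = table.groupby("family")[crit].transform("min")
        table[f"pct_{crit}"] = 100.0 * (table[crit] / best - 1.0)
    return table[["model", "family", "aic", "pct_aic", "bic", "pct_bic"]]
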