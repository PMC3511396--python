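"""Bayesian estimation of the all-random models by MCMC.

The two Bayesian variants (``NL-N-RR-B``, ``L-N-RR-B``) share the equations
of the all-random models; their parameters get broad priors —
``mu0, mu1 ~ N(0, 1000)`` (variance 1000, so prior SD ~= 31.6, conventionally
reported as 32) and ``tau, sigma0, sigma1 ~ U(0, 100)`` — and are sampled by
a Metropolis-within-Gibbs scheme:

* random-walk updates for ``mu0``, ``mu1`` and the log-transformed SDs
  (with the Jacobian of the log transform included);
* a blocked, vectorized random-walk update of each publication's latent
  effects ``(alpha0_i, alpha1_i)``, which are conditionally independent
  across publications;
* likelihood-invariant "shift" moves that translate a mean parameter and
  all its latent deviations in opposite directions (``mu -> mu + delta``,
  ``alpha_i -> alpha_i - delta``), which decorrelates the ridge between a
  population mean and its random effects;
* proposal scales adapted toward standard acceptance targets during
  burn-in only, so the post-burn-in chain keeps detailed balance.

Convergence is monitored with the Gelman-Rubin potential scale reduction
factor and model fit with the deviance information criterion (DIC).  The
deviance underlying DIC conditions on the latent random effects (the
convention of the BUGS family of samplers); this choice changes the
effective number of parameters pD and is therefore stated here explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .ml_inference import as_pubdata
from .model_suite import ModelSpec, ParamSet, mean_response
from .uncertainty_ensemble import UncertaintyBand

__all__ = [
    "PriorSpec",
    "DEFAULT_PRIORS",
    "PosteriorSample",
    "log_posterior",
    "run_mcmc",
    "gelman_rubin",
    "dic",
    "credibility_band",
]

_LOG_2PI = math.log(2.0 * math.pi)

PARAM_NAMES = ("mu0", "mu1", "sigma0", "sigma1", "tau")


@dataclass(frozen=True)
class PriorSpec:
    """Priors: normal for the means, uniform for the SDs."""

    mu_mean: float = 0.0
    mu_var: float = 1000.0
    sd_lower: float = 0.0
    sd_upper: float = 100.0

    @property
    def mu_sd(self) -> float:
        return math.sqrt(self.mu_var)

    def log_prior_mu(self, value: float) -> float:
        return -0.5 * (_LOG_2PI + math.log(self.mu_var)) - 0.5 * value**2 / self.mu_var

    def in_sd_support(self, value: float) -> bool:
        return self.sd_lower < value < self.sd_upper


DEFAULT_PRIORS = PriorSpec()


def _cond_pub_ll(linear, Xp, Yp, mask, counts, mu0, mu1, tau, a0, a1):
    """Per-publication conditional data log-likelihood given the latents."""
    if Xp.shape[0] == 0:
        return np.zeros(0)
    with np.errstate(over="ignore"):
        eta = mu0 + a0[:, None] + (mu1 + a1[:, None]) * Xp
        mean = eta if linear else np.exp(eta)
        resid = np.where(mask > 0, Yp - mean, 0.0)
        ss = np.einsum("ij,ij->i", resid, resid)
    return -0.5 * counts * (_LOG_2PI + 2.0 * math.log(tau)) - 0.5 * ss / tau**2


def log_posterior(
    spec: ModelSpec,
    params: ParamSet,
    latents: tuple[np.ndarray, np.ndarray],
    data,
    priors: PriorSpec = DEFAULT_PRIORS,
) -> float:
    """Unnormalized log posterior on the natural parameter scale.

    Sum of the conditional data log-likelihood given the latent effects, the
    latent Gaussian log-density, and the prior log-density; ``-inf`` outside
    the prior support.
    """
    if not (spec.random_intercept and spec.random_slope):
        raise ValueError("the Bayesian models have both random effects")
    for sd in (params.sigma0, params.sigma1, params.tau):
        if not priors.in_sd_support(sd):
            return -math.inf
    pub = as_pubdata(data)
    a0, a1 = (np.asarray(v, dtype=float) for v in latents)
    if len(a0) != pub.n_publications or len(a1) != pub.n_publications:
        raise ValueError("latent vectors must match the publication count")
    Xp, Yp, mask, counts = pub.padded()
    ll = float(
        np.sum(
            _cond_pub_ll(
                spec.linear, Xp, Yp, mask, counts,
                params.mu0, params.mu1, params.tau, a0, a1,
            )
        )
    )
    lat = float(
        -0.5 * len(a0) * (_LOG_2PI + 2.0 * math.log(params.sigma0))
        - 0.5 * np.sum(a0**2) / params.sigma0**2
        - 0.5 * len(a1) * (_LOG_2PI + 2.0 * math.log(params.sigma1))
        - 0.5 * np.sum(a1**2) / params.sigma1**2
    )
    prior = priors.log_prior_mu(params.mu0) + priors.log_prior_mu(params.mu1)
    prior += -3.0 * math.log(priors.sd_upper - priors.sd_lower)
    return ll + lat + prior


@dataclass
class PosteriorSample:
    """MCMC output: draws by chain plus diagnostics."""

    spec: ModelSpec
    draws: dict[str, np.ndarray]  # name -> (chains, n_kept)
    latent_draws: dict[str, np.ndarray]  # name -> (chains, n_kept, P)
    deviance: np.ndarray  # (chains, n_kept), conditional on latents
    pub_ids: list[str]
    n_chains: int
    n_iter: int
    n_burnin: int
    thin: int
    seed: int
    psrf: dict[str, float] = field(default_factory=dict)
    acceptance: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def flat(self, name: str) -> np.ndarray:
        """All chains pooled for one parameter."""
        return self.draws[name].reshape(-1)

    def posterior_mean_params(self) -> ParamSet:
        return ParamSet(**{name: float(np.mean(self.flat(name))) for name in PARAM_NAMES})

    def summary(self) -> pd.DataFrame:
        rows = []
        for name in PARAM_NAMES:
            pooled = self.flat(name)
            rows.append(
                {
                    "parameter": name,
                    "mean": float(np.mean(pooled)),
                    "sd": float(np.std(pooled, ddof=1)),
                    "q2.5": float(np.percentile(pooled, 2.5)),
                    "q97.5": float(np.percentile(pooled, 97.5)),
                    "psrf": self.psrf.get(name, float("nan")),
                }
            )
        return pd.DataFrame(rows)


def gelman_rubin(chains) -> float:
    """Potential scale reduction factor for one parameter.

    Uses the second half of each chain; values near 1 indicate that the
    between-chain variance is consistent with the within-chain variance.
    """
    arrs = [np.asarray(c, dtype=float).ravel() for c in np.asarray(chains, dtype=float)] \
        if isinstance(chains, np.ndarray) and np.asarray(chains).ndim == 2 \
        else [np.asarray(c, dtype=float).ravel() for c in chains]
    m = len(arrs)
    if m < 2:
        raise ValueError("Gelman-Rubin needs at least two chains")
    lengths = {len(a) for a in arrs}
    if len(lengths) != 1:
        raise ValueError("chains must have equal lengths")
    n_full = lengths.pop()
    if n_full < 10:
        raise ValueError("chains too short for a meaningful diagnostic")
    halves = np.vstack([a[n_full // 2 :] for a in arrs])
    n = halves.shape[1]
    within = float(np.mean(np.var(halves, axis=1, ddof=1)))
    between_over_n = float(np.var(np.mean(halves, axis=1), ddof=1))
    if within == 0.0:
        return 1.0 if between_over_n == 0.0 else math.inf
    var_plus = (n - 1) / n * within + between_over_n
    # clamp at 1: the finite-sample estimator can dip slightly below
    return max(1.0, math.sqrt(var_plus / within))


def _crude_center(linear: bool, x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    if len(y) == 0:
        return 0.0, 0.0, 1.0
    target = y if linear else np.log(np.clip(y, 0.05, None))
    if np.var(x) > 0:
        slope = float(np.cov(x, target, bias=True)[0, 1] / np.var(x))
        intercept = float(np.mean(target) - slope * np.mean(x))
    else:
        slope, intercept = 0.0, float(np.mean(target))
    if linear:
        resid_sd = float(np.std(y - intercept - slope * x)) or 1.0
    else:
        resid_sd = float(np.std(y - np.exp(intercept + slope * x))) or 1.0
    return intercept, slope, resid_sd


def run_mcmc(
    spec: ModelSpec,
    data,
    priors: PriorSpec = DEFAULT_PRIORS,
    n_chains: int = 3,
    n_iter: int = 20_000,
    burnin: int | None = None,
    thin: int = 10,
    seed: int = 0,
) -> PosteriorSample:
    """Sample the posterior of a Bayesian all-random model.

    Chains start overdispersed from distinct seed streams; proposal scales
    adapt during burn-in (default: first half) and are then frozen.  With a
    zero-length dataset the sampler draws from the prior.  Bit-reproducible
    from ``seed``.
    """
    if not spec.bayesian:
        raise ValueError(f"{spec.name} is not one of the Bayesian models")
    if n_chains < 1 or n_iter < 100:
        raise ValueError("need n_chains >= 1 and n_iter >= 100")
    burnin = n_iter // 2 if burnin is None else burnin
    if not 0 < burnin < n_iter:
        raise ValueError("burnin must lie strictly inside (0, n_iter)")

    pub = as_pubdata(data)
    Xp, Yp, mask, counts = pub.padded()
    P = pub.n_publications
    linear = spec.linear
    n_kept = len(range(burnin, n_iter, thin))

    center_mu0, center_mu1, center_tau = _crude_center(linear, pub.all_x(), pub.all_y())

    draws = {name: np.empty((n_chains, n_kept)) for name in PARAM_NAMES}
    latent_draws = {
        "alpha0": np.empty((n_chains, n_kept, P)),
        "alpha1": np.empty((n_chains, n_kept, P)),
    }
    deviance = np.empty((n_chains, n_kept))
    acc_totals: dict[str, list[float]] = {}

    scalar_names = ("mu0", "mu1", "log_sigma0", "log_sigma1", "log_tau")

    for chain in range(n_chains):
        rng = np.random.default_rng([int(seed), chain])
        # overdispersed but support-respecting starting point
        mu0 = center_mu0 + rng.normal(0.0, 1.0)
        mu1 = center_mu1 + rng.normal(0.0, max(0.002, abs(center_mu1)))
        ls0 = math.log(np.clip(math.exp(rng.normal(0.0, 0.7)), 0.05, 50.0))
        ls1 = math.log(
            np.clip(abs(center_mu1) * math.exp(rng.normal(0.0, 0.7)) + 1e-4, 1e-4, 50.0)
        )
        lt = math.log(np.clip(center_tau * math.exp(rng.normal(0.0, 0.5)), 0.05, 50.0))
        a0 = rng.normal(0.0, math.exp(ls0), P)
        a1 = rng.normal(0.0, math.exp(ls1), P)

        pub_ll = _cond_pub_ll(linear, Xp, Yp, mask, counts, mu0, mu1, math.exp(lt), a0, a1)

        scales = {"mu0": 0.1, "mu1": 0.002, "log_sigma0": 0.3, "log_sigma1": 0.3,
                  "log_tau": 0.1, "latent": 0.5, "shift0": 0.2, "shift1": 0.002}
        block_names = (*scalar_names, "latent", "shift0", "shift1")
        acc_counts = {k: 0 for k in block_names}
        acc_window = {k: 0.0 for k in block_names}
        window = 100

        def lp_lsd(l: float) -> float:
            # density of log sigma when sigma ~ U(lower, upper)
            if not priors.in_sd_support(math.exp(l)):
                return -math.inf
            return l - math.log(priors.sd_upper - priors.sd_lower)

        def lat_prior_sum(vals: np.ndarray, lsd: float) -> float:
            sd = math.exp(lsd)
            return float(-0.5 * len(vals) * (_LOG_2PI + 2.0 * lsd)
                         - 0.5 * np.sum(vals**2) / sd**2)

        keep_slot = 0
        for t in range(n_iter):
            # --- scalar parameters -------------------------------------
            for name in scalar_names:
                prop = rng.normal(0.0, scales[name])
                if name == "mu0":
                    cand = mu0 + prop
                    new_ll = _cond_pub_ll(linear, Xp, Yp, mask, counts, cand, mu1,
                                          math.exp(lt), a0, a1)
                    delta = float(np.sum(new_ll) - np.sum(pub_ll))
                    delta += priors.log_prior_mu(cand) - priors.log_prior_mu(mu0)
                    if math.log(rng.random()) < delta:
                        mu0, pub_ll = cand, new_ll
                        acc_window[name] += 1
                elif name == "mu1":
                    cand = mu1 + prop
                    new_ll = _cond_pub_ll(linear, Xp, Yp, mask, counts, mu0, cand,
                                          math.exp(lt), a0, a1)
                    delta = float(np.sum(new_ll) - np.sum(pub_ll))
                    delta += priors.log_prior_mu(cand) - priors.log_prior_mu(mu1)
                    if math.log(rng.random()) < delta:
                        mu1, pub_ll = cand, new_ll
                        acc_window[name] += 1
                elif name == "log_tau":
                    cand = lt + prop
                    if not np.isfinite(lp_lsd(cand)):
                        continue
                    new_ll = _cond_pub_ll(linear, Xp, Yp, mask, counts, mu0, mu1,
                                          math.exp(cand), a0, a1)
                    delta = float(np.sum(new_ll) - np.sum(pub_ll))
                    delta += lp_lsd(cand) - lp_lsd(lt)
                    if math.log(rng.random()) < delta:
                        lt, pub_ll = cand, new_ll
                        acc_window[name] += 1
                elif name == "log_sigma0":
                    cand = ls0 + prop
                    if not np.isfinite(lp_lsd(cand)):
                        continue
                    delta = lat_prior_sum(a0, cand) - lat_prior_sum(a0, ls0)
                    delta += lp_lsd(cand) - lp_lsd(ls0)
                    if math.log(rng.random()) < delta:
                        ls0 = cand
                        acc_window[name] += 1
                else:  # log_sigma1
                    cand = ls1 + prop
                    if not np.isfinite(lp_lsd(cand)):
                        continue
                    delta = lat_prior_sum(a1, cand) - lat_prior_sum(a1, ls1)
                    delta += lp_lsd(cand) - lp_lsd(ls1)
                    if math.log(rng.random()) < delta:
                        ls1 = cand
                        acc_window[name] += 1

            # --- latent blocks (conditionally independent over pubs) ---
            if P > 0:
                s0 = math.exp(ls0)
                s1 = math.exp(ls1)
                cand0 = a0 + scales["latent"] * s0 * rng.normal(size=P)
                cand1 = a1 + scales["latent"] * s1 * rng.normal(size=P)
                new_ll = _cond_pub_ll(linear, Xp, Yp, mask, counts, mu0, mu1,
                                      math.exp(lt), cand0, cand1)
                delta = (
                    new_ll - pub_ll
                    - 0.5 * (cand0**2 - a0**2) / s0**2
                    - 0.5 * (cand1**2 - a1**2) / s1**2
                )
                accept = np.log(rng.random(P)) < delta
                a0 = np.where(accept, cand0, a0)
                a1 = np.where(accept, cand1, a1)
                pub_ll = np.where(accept, new_ll, pub_ll)
                acc_window["latent"] += float(np.mean(accept))

                # shift moves: translate (mu, alpha) along the likelihood-
                # invariant ridge; only the latent prior and mu prior change
                dlt = rng.normal(0.0, scales["shift0"])
                delta = lat_prior_sum(a0 - dlt, ls0) - lat_prior_sum(a0, ls0)
                delta += priors.log_prior_mu(mu0 + dlt) - priors.log_prior_mu(mu0)
                if math.log(rng.random()) < delta:
                    mu0 += dlt
                    a0 = a0 - dlt
                    acc_window["shift0"] += 1
                dlt = rng.normal(0.0, scales["shift1"])
                delta = lat_prior_sum(a1 - dlt, ls1) - lat_prior_sum(a1, ls1)
                delta += priors.log_prior_mu(mu1 + dlt) - priors.log_prior_mu(mu1)
                if math.log(rng.random()) < delta:
                    mu1 += dlt
                    a1 = a1 - dlt
                    acc_window["shift1"] += 1

            # --- adaptation (burn-in only) -----------------------------
            if t < burnin and (t + 1) % window == 0:
                for name in block_names:
                    if P == 0 and name in ("latent", "shift0", "shift1"):
                        continue
                    target = 0.30 if name == "latent" else 0.44
                    rate = acc_window[name] / window
                    scales[name] = float(
                        np.clip(scales[name] * math.exp(rate - target), 1e-8, 1e4)
                    )
                    acc_counts[name] += acc_window[name]
                    acc_window[name] = 0.0

            # --- storage -----------------------------------------------
            if t >= burnin and (t - burnin) % thin == 0:
                draws["mu0"][chain, keep_slot] = mu0
                draws["mu1"][chain, keep_slot] = mu1
                draws["sigma0"][chain, keep_slot] = math.exp(ls0)
                draws["sigma1"][chain, keep_slot] = math.exp(ls1)
                draws["tau"][chain, keep_slot] = math.exp(lt)
                latent_draws["alpha0"][chain, keep_slot] = a0
                latent_draws["alpha1"][chain, keep_slot] = a1
                deviance[chain, keep_slot] = -2.0 * float(np.sum(pub_ll))
                keep_slot += 1

        for name in block_names:
            if P == 0 and name in ("latent", "shift0", "shift1"):
                continue
            acc_counts[name] += acc_window[name]
            acc_totals.setdefault(name, []).append(acc_counts[name] / n_iter)

    acceptance = {name: float(np.mean(vals)) for name, vals in acc_totals.items()}
    warnings_list = [
        f"acceptance rate for {name} is {rate:.2f}, outside (0.05, 0.95)"
        for name, rate in acceptance.items()
        if not 0.05 < rate < 0.95
    ]

    psrf = {}
    if n_chains >= 2:
        for name in PARAM_NAMES:
            psrf[name] = gelman_rubin(draws[name])

    return PosteriorSample(
        spec=spec,
        draws=draws,
        latent_draws=latent_draws,
        deviance=deviance,
        pub_ids=list(pub.ids),
        n_chains=n_chains,
        n_iter=n_iter,
        n_burnin=burnin,
        thin=thin,
        seed=seed,
        psrf=psrf,
        acceptance=acceptance,
        warnings=warnings_list,
    )


def dic(
    sample: PosteriorSample,
    data,
    spec: ModelSpec | None = None,
    return_components: bool = False,
):
    """Deviance information criterion, DIC = Dbar + pD.

    The deviance conditions on the latent random effects (stated choice, see
    module docstring): ``D = -2 log p(y | mu, tau, alpha)``.  ``Dbar`` is the
    posterior mean deviance and ``pD = Dbar - D(posterior means)`` with the
    plug-in evaluated at the posterior means of the parameters *and*
    latents.
    """
    spec = sample.spec if spec is None else spec
    pub = as_pubdata(data)
    Xp, Yp, mask, counts = pub.padded()
    dbar = float(np.mean(sample.deviance))
    mean_params = sample.posterior_mean_params()
    a0_hat = np.mean(sample.latent_draws["alpha0"], axis=(0, 1))
    a1_hat = np.mean(sample.latent_draws["alpha1"], axis=(0, 1))
    dhat = -2.0 * float(
        np.sum(
            _cond_pub_ll(
                spec.linear, Xp, Yp, mask, counts,
                mean_params.mu0, mean_params.mu1, mean_params.tau, a0_hat, a1_hat,
            )
        )
    )
    p_d = dbar - dhat
    value = dbar + p_d
    if return_components:
        return {"dic": value, "dbar": dbar, "dhat": dhat, "pd": p_d}
    return value


def credibility_band(
    sample: PosteriorSample,
    dose_grid,
    subtract_background: bool = True,
) -> UncertaintyBand:
    """95% credibility band of the population-level response.

    Per dose, the 2.5/50/97.5 percentiles of the mean response evaluated at
    each posterior draw of ``(mu0, mu1)``; with ``subtract_background``
    each draw's zero-dose response is subtracted first, so the band
    describes emission due to applied N.
    """
    grid = np.asarray(dose_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("dose grid is empty")
    mu0 = sample.flat("mu0")[:, None]
    mu1 = sample.flat("mu1")[:, None]
    eta = mu0 + mu1 * grid[None, :]
    preds = eta if sample.spec.linear else np.exp(eta)
    if subtract_background:
        bg = mu0 if sample.spec.linear else np.exp(mu0)
        preds = preds - bg
    lower, point, upper = np.percentile(preds, [2.5, 50.0, 97.5], axis=0)
    return UncertaintyBand(
        model=sample.spec.name,
        dose_grid=grid,
        point=point,
        lower=lower,
        upper=upper,
        background_subtracted=subtract_background,
        provenance={
            "method": "posterior credibility",
            "n_draws": int(mu0.size),
            "seed": sample.seed,
        },
    )
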