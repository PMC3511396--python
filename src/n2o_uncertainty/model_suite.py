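"""Response models relating N2O emission to the amount of applied nitrogen.

Thirteen model structures are considered, crossing four design choices:

* response function — exponential (``NL`` prefix) or linear (``L`` prefix);
* presence of the applied-N dose as an explanatory variable (``N`` vs ``0``);
* fixed (``F``) or random (``R``) background emission (the intercept);
* fixed or random applied-N effect (the slope).

The two ``-B`` variants share the equations of the all-random models but are
estimated by MCMC (see :mod:`n2o_uncertainty.bayes_inference`).

For a measurement :math:`Y_{ijk}` at dose :math:`X_{ij}` in publication *i*,
the mean response is

.. math::

    m(X) = (\\mu_0 + \\alpha_{0i}) + (\\mu_1 + \\alpha_{1i}) X
    \\quad\\text{(linear)},\\qquad
    m(X) = e^{(\\mu_0 + \\alpha_{0i}) + (\\mu_1 + \\alpha_{1i}) X}
    \\quad\\text{(exponential)},

with random effects :math:`\\alpha_{0i}\\sim N(0,\\sigma_0^2)`,
:math:`\\alpha_{1i}\\sim N(0,\\sigma_1^2)` and residuals
:math:`\\varepsilon_{ijk}\\sim N(0,\\tau^2)`, all independent.

This module also holds the emission-factor (EF) arithmetic derived from the
fitted parameters: emissions due to applied N, marginal and average EFs, the
dose at which the marginal EF crosses a target value, and the IPCC-Tier 1
constant-EF method (EF = 0.01, uncertainty range 0.003-0.03) used as the
benchmark throughout.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np

__all__ = [
    "ModelSpec",
    "ParamSet",
    "MODELS",
    "MODEL_NAMES",
    "PUBLISHED_ESTIMATES",
    "get_model",
    "mean_response",
    "emission_due_to_N",
    "emission_reduction",
    "marginal_EF",
    "average_EF",
    "ef_threshold_dose",
    "ipcc_tier1",
    "ipcc_range",
    "round_dose",
]


@dataclass(frozen=True)
class ModelSpec:
    """Structure of one emission-response model.

    Attributes
    ----------
    name:
        Canonical name, e.g. ``"NL-N-RR"`` (exponential, applied-N term,
        random intercept, random slope).
    linear:
        Linear mean response if True, exponential otherwise.
    uses_N:
        Whether the applied-N dose enters the mean.
    random_intercept, random_slope:
        Whether the intercept / N-effect vary between publications.
    bayesian:
        Estimated by MCMC rather than approximate maximum likelihood.
    """

    name: str
    linear: bool
    uses_N: bool
    random_intercept: bool
    random_slope: bool
    bayesian: bool = False

    def __post_init__(self) -> None:
        if self.random_slope and not self.uses_N:
            raise ValueError(
                f"{self.name}: a random applied-N effect requires the applied-N term"
            )

    @property
    def family(self) -> str:
        """``"linear"`` or ``"nonlinear"`` — the model-selection family."""
        return "linear" if self.linear else "nonlinear"

    @property
    def n_random(self) -> int:
        return int(self.random_intercept) + int(self.random_slope)

    @property
    def n_params(self) -> int:
        """Number of free parameters: mu0 and tau always, plus mu1/sigma0/sigma1."""
        return (
            2
            + int(self.uses_N)
            + int(self.random_intercept)
            + int(self.random_slope)
        )


def _build_registry() -> dict[str, ModelSpec]:
    rows = [
        # name, linear, uses_N, rand_int, rand_slope, bayesian
        ("NL-N-FF", False, True, False, False, False),
        ("NL-0-R", False, False, True, False, False),
        ("NL-N-RF", False, True, True, False, False),
        ("NL-N-FR", False, True, False, True, False),
        ("NL-N-RR", False, True, True, True, False),
        ("NL-N-RR-B", False, True, True, True, True),
        ("L-0-F", True, False, False, False, False),
        ("L-N-FF", True, True, False, False, False),
        ("L-0-R", True, False, True, False, False),
        ("L-N-RF", True, True, True, False, False),
        ("L-N-FR", True, True, False, True, False),
        ("L-N-RR", True, True, True, True, False),
        ("L-N-RR-B", True, True, True, True, True),
    ]
    return {name: ModelSpec(name, *rest) for name, *rest in rows}


MODELS: dict[str, ModelSpec] = _build_registry()
MODEL_NAMES: tuple[str, ...] = tuple(MODELS)


def get_model(name: str) -> ModelSpec:
    """Look up a model structure by its canonical name."""
    try:
        return MODELS[name]
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; choose one of {', '.join(MODEL_NAMES)}"
        ) from None


@dataclass(frozen=True)
class ParamSet:
    """Population parameters of one model.

    mu0
        Mean background emission (log scale for exponential models),
        kg N2O-N ha-1 yr-1 for linear models.
    mu1
        Mean applied-N effect per kg N ha-1 (the EF itself for linear models).
    sigma0, sigma1
        Between-publication SDs of the intercept and N effect.
    tau
        Residual SD, kg N2O-N ha-1 yr-1.
    """

    mu0: float
    mu1: float = 0.0
    sigma0: float = 0.0
    sigma1: float = 0.0
    tau: float = 0.0

    def __post_init__(self) -> None:
        for field_name in ("sigma0", "sigma1", "tau"):
            if getattr(self, field_name) < 0:
                raise ValueError(f"{field_name} must be nonnegative")

    def validate_for(self, spec: ModelSpec) -> None:
        """Check consistency with a model structure.

        Raises ``ValueError`` when a between-publication SD is supplied for
        an effect the structure declares fixed.
        """
        if self.sigma0 != 0.0 and not spec.random_intercept:
            raise ValueError(f"{spec.name} has a fixed intercept; sigma0 must be 0")
        if self.sigma1 != 0.0 and not spec.random_slope:
            raise ValueError(f"{spec.name} has a fixed N effect; sigma1 must be 0")

    def as_dict(self) -> dict[str, float]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "ParamSet":
        return cls(**{k: float(v) for k, v in d.items()})


#: Parameter estimates obtained when these thirteen models were fitted to a
#: published global compilation of 985 field N2O measurements from 203
#: publications.  Used as generating truths for simulation studies, demos and
#: worked examples; they are inputs, not quantities this package re-estimates
#: from that (non-shipped) dataset.
PUBLISHED_ESTIMATES: dict[str, ParamSet] = {
    "NL-N-FF": ParamSet(mu0=0.25, mu1=0.0042, tau=3.96),
    "NL-0-R": ParamSet(mu0=0.87, sigma0=0.84, tau=2.84),
    "NL-N-RF": ParamSet(mu0=-0.068, mu1=0.0050, sigma0=0.83, tau=2.09),
    "NL-N-FR": ParamSet(mu0=0.31, mu1=0.0033, sigma1=0.0043, tau=2.13),
    "NL-N-RR": ParamSet(mu0=0.19, mu1=0.0037, sigma0=0.72, sigma1=0.0025, tau=1.94),
    "NL-N-RR-B": ParamSet(mu0=-0.21, mu1=0.0038, sigma0=0.92, sigma1=0.0032, tau=1.91),
    "L-0-F": ParamSet(mu0=2.40, tau=4.26),
    "L-N-FF": ParamSet(mu0=0.69, mu1=0.0138, tau=3.96),
    "L-0-R": ParamSet(mu0=2.78, sigma0=3.44, tau=2.91),
    "L-N-RF": ParamSet(mu0=0.99, mu1=0.0130, sigma0=3.16, tau=2.67),
    "L-N-FR": ParamSet(mu0=1.09, mu1=0.0113, sigma1=0.0195, tau=2.12),
    "L-N-RR": ParamSet(mu0=1.04, mu1=0.0117, sigma0=0.70, sigma1=0.0187, tau=2.08),
    "L-N-RR-B": ParamSet(mu0=1.04, mu1=0.0117, sigma0=0.76, sigma1=0.0189, tau=2.08),
}


def _as_dose(dose):
    arr = np.asarray(dose, dtype=float)
    if np.any(arr < 0):
        raise ValueError("applied-N dose must be nonnegative")
    return arr


def _maybe_scalar(value, template):
    if np.isscalar(template) or np.ndim(template) == 0:
        return float(value)
    return value


def mean_response(
    spec: ModelSpec,
    params: ParamSet,
    dose,
    a0: float = 0.0,
    a1: float = 0.0,
):
    """Mean N2O emission (kg N2O-N ha-1 yr-1) at one or more doses.

    ``a0`` and ``a1`` are publication-specific deviations of the intercept and
    N effect; leave them at 0 for the population-level response.
    """
    x = _as_dose(dose)
    eta = (params.mu0 + a0) + np.zeros_like(x)
    if spec.uses_N:
        eta = eta + (params.mu1 + a1) * x
    out = eta if spec.linear else np.exp(eta)
    return _maybe_scalar(out, dose)


def emission_due_to_N(spec: ModelSpec, params: ParamSet, dose):
    """Emission attributable to fertilization: response at ``dose`` minus the
    background (response at dose 0)."""
    if not spec.uses_N:
        raise ValueError(
            f"{spec.name} has no applied-N term; emission due to N is undefined"
        )
    x = _as_dose(dose)
    out = mean_response(spec, params, x) - mean_response(spec, params, 0.0)
    return _maybe_scalar(out, dose)


def emission_reduction(
    spec: ModelSpec, params: ParamSet, dose_from: float, dose_to: float
) -> float:
    """Reduction in predicted emission when the dose drops from
    ``dose_from`` to ``dose_to``."""
    if dose_from < dose_to:
        raise ValueError("dose_from must be >= dose_to")
    return float(
        mean_response(spec, params, dose_from) - mean_response(spec, params, dose_to)
    )


def marginal_EF(spec: ModelSpec, params: ParamSet, dose):
    """Marginal emission factor: d(mean response)/d(dose).

    Constant ``mu1`` for linear models; ``mu1 * exp(mu0 + mu1 X)`` for
    exponential models, so it grows with the dose when ``mu1 > 0``.
    """
    if not spec.uses_N:
        raise ValueError(f"{spec.name} has no applied-N term; EF is undefined")
    x = _as_dose(dose)
    if spec.linear:
        out = params.mu1 + np.zeros_like(x)
    else:
        out = params.mu1 * np.exp(params.mu0 + params.mu1 * x)
    return _maybe_scalar(out, dose)


def average_EF(spec: ModelSpec, params: ParamSet, dose):
    """Average emission factor: emission due to N divided by the dose."""
    x = _as_dose(dose)
    if np.any(x == 0):
        raise ValueError("average EF is undefined at dose 0")
    out = emission_due_to_N(spec, params, x) / x
    return _maybe_scalar(out, dose)


def ef_threshold_dose(
    spec: ModelSpec, params: ParamSet, target_EF: float = 0.01
) -> float:
    """Dose at which the marginal EF of an exponential model reaches
    ``target_EF``.

    Solves ``mu1 * exp(mu0 + mu1 X) = target`` in closed form:
    ``X* = (ln(target/mu1) - mu0) / mu1``.  Below ``X*`` the model's marginal
    EF is smaller than the target (e.g. the IPCC-Tier 1 constant of 1%).
    """
    if spec.linear:
        raise ValueError("marginal EF of a linear model is constant; no threshold")
    if not spec.uses_N or params.mu1 <= 0:
        raise ValueError("threshold requires an applied-N term with mu1 > 0")
    ef0 = marginal_EF(spec, params, 0.0)
    if target_EF < ef0:
        raise ValueError(
            f"target EF {target_EF} is below the marginal EF at dose 0 ({ef0:.4g})"
        )
    return (math.log(target_EF / params.mu1) - params.mu0) / params.mu1


def round_dose(dose: float, nearest: float = 10.0) -> float:
    """Round a dose to the nearest ``nearest`` kg N ha-1 (reporting aid)."""
    return float(round(dose / nearest) * nearest)


def ipcc_tier1(dose, EF: float = 0.01):
    """IPCC-Tier 1 emission due to applied N: ``EF * dose``."""
    if not 0.0 < EF < 1.0:
        raise ValueError("EF must lie in (0, 1)")
    x = _as_dose(dose)
    return _maybe_scalar(EF * x, dose)


def ipcc_range(dose, EF_low: float = 0.003, EF_high: float = 0.03):
    """IPCC-Tier 1 uncertainty range from the published EF bounds."""
    return ipcc_tier1(dose, EF_low), ipcc_tier1(dose, EF_high)
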