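"""Bootstrap confidence bands, the multi-model ensemble range and the
IPCC-Tier 1 comparison.

Confidence bands for the non-Bayesian models come from a cluster bootstrap:
whole publications are resampled with replacement (observation-level
resampling would break the grouping the mixed models rely on, but is
available behind ``resample_unit="observation"``), the model is refitted to
each resample, and pointwise 2.5/97.5 percentiles of the background-
subtracted predictions form the band.  Bayesian members contribute
credibility bands computed from their posterior draws
(:func:`n2o_uncertainty.bayes_inference.credibility_band`).

The ensemble range takes, at each dose, the minimum of the member lower
limits and the maximum of the member upper limits — interpretable as
best-case and worst-case emission scenarios — plus the envelope of the
member point predictions (uncertainty in the model equations alone).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .ml_inference import FitResult, PubData, as_pubdata, fit_ml
from .model_suite import ModelSpec, ParamSet, ipcc_range, ipcc_tier1, mean_response

logger = logging.getLogger(__name__)

__all__ = [
    "UncertaintyBand",
    "EnsembleRange",
    "default_dose_grid",
    "bootstrap_band",
    "select_ensemble",
    "ensemble_range",
    "compare_with_ipcc",
    "predictive_percentiles",
]


def default_dose_grid(step: float = 5.0, max_dose: float = 500.0) -> np.ndarray:
    """Default reporting grid: 0 to 500 kg N ha-1 in steps of ``step``."""
    return np.arange(0.0, max_dose + 0.5 * step, step)


@dataclass
class UncertaintyBand:
    """Pointwise 95% band of predicted emissions for one model."""

    model: str
    dose_grid: np.ndarray
    point: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    background_subtracted: bool
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dose_grid = np.asarray(self.dose_grid, dtype=float)
        self.point = np.asarray(self.point, dtype=float)
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        shapes = {a.shape for a in (self.dose_grid, self.point, self.lower, self.upper)}
        if len(shapes) != 1:
            raise ValueError("band arrays must share the dose-grid shape")
        if np.any(self.lower > self.point + 1e-9) or np.any(self.point > self.upper + 1e-9):
            raise ValueError("band must satisfy lower <= point <= upper")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "model": self.model,
                "dose": self.dose_grid,
                "point": self.point,
                "lower": self.lower,
                "upper": self.upper,
            }
        )


@dataclass
class EnsembleRange:
    """Best-case / worst-case envelope over the selected models."""

    members: list[str]
    dose_grid: np.ndarray
    equation_low: np.ndarray
    equation_high: np.ndarray
    full_low: np.ndarray
    full_high: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.full_low > self.equation_low + 1e-9) or np.any(
            self.equation_high > self.full_high + 1e-9
        ):
            raise ValueError("equation range must nest inside the full range")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "dose": self.dose_grid,
                "equation_low": self.equation_low,
                "equation_high": self.equation_high,
                "full_low": self.full_low,
                "full_high": self.full_high,
            }
        )


def _band_predictions(
    spec: ModelSpec, params: ParamSet, grid: np.ndarray, subtract_background: bool
) -> np.ndarray:
    pred = mean_response(spec, params, grid)
    if subtract_background:
        pred = pred - mean_response(spec, params, 0.0)
    return np.asarray(pred, dtype=float)


def bootstrap_band(
    spec: ModelSpec,
    data,
    B: int = 500,
    dose_grid: np.ndarray | None = None,
    seed: int = 0,
    resample_unit: str = "publication",
    subtract_background: bool = True,
    n_nodes: int = 9,
    max_failed_fraction: float = 0.1,
) -> UncertaintyBand:
    """Cluster-bootstrap 95% confidence band for one non-Bayesian model.

    ``B`` resamples are drawn with replacement at the publication (default)
    or observation level; the model is refitted to each resample
    (warm-started at the full-data estimates) and the band is formed from
    the 2.5/97.5 percentiles of the refitted predictions.  Refits that fail
    to converge are dropped and counted; more than ``max_failed_fraction``
    failures aborts with diagnostics.
    """
    if spec.bayesian:
        raise ValueError("bootstrap bands apply to non-Bayesian models")
    if resample_unit not in ("publication", "observation"):
        raise ValueError("resample_unit must be 'publication' or 'observation'")
    grid = default_dose_grid() if dose_grid is None else np.asarray(dose_grid, float)
    pub = as_pubdata(data)
    rng = np.random.default_rng(seed)

    full_fit = fit_ml(spec, pub, n_nodes=n_nodes)
    init = full_fit.estimates

    preds = np.empty((B, len(grid)))
    n_failed = 0
    kept = 0
    for b in range(B):
        if resample_unit == "publication":
            idx = rng.integers(0, pub.n_publications, pub.n_publications)
            sample = PubData(
                ids=[f"{pub.ids[i]}#{r}" for r, i in enumerate(idx)],
                x=[pub.x[i] for i in idx],
                y=[pub.y[i] for i in idx],
            )
        else:
            x = pub.all_x()
            y = pub.all_y()
            idx = rng.integers(0, len(y), len(y))
            sample = PubData(ids=["obs"], x=[x[idx]], y=[y[idx]])
        try:
            fit = fit_ml(spec, sample, init=init, n_nodes=n_nodes)
        except (ValueError, RuntimeError) as exc:
            logger.warning("bootstrap refit %d failed: %s", b, exc)
            n_failed += 1
            continue
        if not fit.converged:
            logger.warning("bootstrap refit %d did not converge; dropped", b)
            n_failed += 1
            continue
        preds[kept] = _band_predictions(spec, fit.estimates, grid, subtract_background)
        kept += 1
    if n_failed > max_failed_fraction * B:
        raise RuntimeError(
            f"{n_failed}/{B} bootstrap refits failed for {spec.name}; "
            "data may be too sparse for this model"
        )
    preds = preds[:kept]
    lower, point, upper = np.percentile(preds, [2.5, 50.0, 97.5], axis=0)
    return UncertaintyBand(
        model=spec.name,
        dose_grid=grid,
        point=point,
        lower=lower,
        upper=upper,
        background_subtracted=subtract_background,
        provenance={
            "method": "cluster bootstrap" if resample_unit == "publication" else "bootstrap",
            "B": B,
            "seed": seed,
            "failed_refits": n_failed,
            "full_fit": full_fit.estimates.as_dict(),
        },
    )


def select_ensemble(fits: Sequence[FitResult], threshold: float = 10.0) -> list[str]:
    """Select ensemble members from the full non-Bayesian fit table.

    Keeps every model whose AIC and BIC are within ``threshold`` percent of
    its family's (linear or nonlinear) best values, then appends the two
    Bayesian counterparts of the all-random models.
    """
    from .ml_inference import model_selection_table

    table = model_selection_table(fits)
    keep = table[(table["pct_aic"] <= threshold) & (table["pct_bic"] <= threshold)]
    selected = list(keep["model"])
    if not selected:
        raise ValueError("no model within the selection threshold")
    selected += ["NL-N-RR-B", "L-N-RR-B"]
    return selected


def ensemble_range(
    bands: Sequence[UncertaintyBand], dose_grid: np.ndarray | None = None
) -> EnsembleRange:
    """Pointwise envelope over member bands (all background-subtracted, all
    on the same dose grid)."""
    if not bands:
        raise ValueError("need at least one band")
    grid = np.asarray(bands[0].dose_grid if dose_grid is None else dose_grid, float)
    for band in bands:
        if band.dose_grid.shape != grid.shape or not np.allclose(band.dose_grid, grid):
            raise ValueError(f"band {band.model} is not on the common dose grid")
        if not band.background_subtracted:
            raise ValueError(f"band {band.model} is not background-subtracted")
    points = np.vstack([b.point for b in bands])
    lowers = np.vstack([b.lower for b in bands])
    uppers = np.vstack([b.upper for b in bands])
    return EnsembleRange(
        members=[b.model for b in bands],
        dose_grid=grid,
        equation_low=points.min(axis=0),
        equation_high=points.max(axis=0),
        full_low=lowers.min(axis=0),
        full_high=uppers.max(axis=0),
    )


def compare_with_ipcc(
    ensemble: EnsembleRange, dose_grid: np.ndarray | None = None
) -> pd.DataFrame:
    """Per-dose comparison of the ensemble envelope with IPCC-Tier 1.

    Reports the constant-EF point estimate (1% of applied N) and range
    (0.3%-3%), whether the 1% line lies inside the ensemble equation range,
    and whether the full ensemble range is contained in the IPCC range.
    """
    grid = ensemble.dose_grid if dose_grid is None else np.asarray(dose_grid, float)
    if dose_grid is not None and not np.allclose(grid, ensemble.dose_grid):
        raise ValueError("dose grid does not match the ensemble grid")
    ipcc_low, ipcc_high = ipcc_range(grid)
    ipcc_point = ipcc_tier1(grid)
    eps = 1e-9
    return pd.DataFrame(
        {
            "dose": grid,
            "ensemble_low": ensemble.full_low,
            "ensemble_high": ensemble.full_high,
            "equation_low": ensemble.equation_low,
            "equation_high": ensemble.equation_high,
            "ipcc_low": ipcc_low,
            "ipcc_point": ipcc_point,
            "ipcc_high": ipcc_high,
            "ipcc_point_in_equation_range": (
                (ipcc_point >= ensemble.equation_low - eps)
                & (ipcc_point <= ensemble.equation_high + eps)
            ),
            "ensemble_within_ipcc": (
                (ensemble.full_low >= ipcc_low - eps)
                & (ensemble.full_high <= ipcc_high + eps)
            ),
        }
    )


def predictive_percentiles(
    spec: ModelSpec,
    params: ParamSet,
    dose: float,
    percentiles: Sequence[float] = (90.0, 95.0, 99.0),
    n_draws: int = 100_000,
    include_residual: bool = False,
    subtract_background: bool = False,
    seed: int = 0,
) -> np.ndarray:
    """Monte-Carlo percentiles of experiment-specific emission at one dose.

    Draws random effects (and, optionally, a residual) and pushes them
    through the mean response, describing the between-experiment spread that
    the population-level confidence bands deliberately exclude.  When
    ``subtract_background`` is set, each draw's own zero-dose response
    (same random intercept, no residual) is subtracted.
    """
    percs = np.asarray(percentiles, dtype=float)
    if np.any(percs <= 0.0) or np.any(percs >= 100.0):
        raise ValueError("percentiles must lie strictly between 0 and 100")
    rng = np.random.default_rng(seed)
    a0 = rng.normal(0.0, params.sigma0, n_draws) if spec.random_intercept else 0.0
    a1 = rng.normal(0.0, params.sigma1, n_draws) if spec.random_slope else 0.0
    eta = params.mu0 + a0
    if spec.uses_N:
        eta = eta + (params.mu1 + a1) * dose
    values = eta if spec.linear else np.exp(eta)
    values = np.broadcast_to(values, (n_draws,)).astype(float)
    if include_residual:
        values = values + rng.normal(0.0, params.tau, n_draws)
    if subtract_background:
        eta0 = params.mu0 + a0
        values = values - (eta0 if spec.linear else np.exp(eta0))
    return np.percentile(values, percs)
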