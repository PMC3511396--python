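"""Synthetic hierarchical datasets with the structure the models assume.

Each simulated publication receives its own random intercept
``alpha0 ~ N(0, sigma0^2)`` and random N-effect ``alpha1 ~ N(0, sigma1^2)``
(zero when the generating model declares the effect fixed), a handful of
applied-N doses, and replicate measurements with residual noise
``eps ~ N(0, tau^2)``.  Negative simulated emissions are kept: the Gaussian
residual model implies them and the likelihoods assume untruncated normals.

The default "world" design emulates the marginal summaries of the global
field-measurement compilation the models were originally fitted to: 203
publications, doses in [0, 500] kg N ha-1 with a point mass at 0 (unfertilized
controls) and a right-skewed positive-dose distribution with median near 100
and mean near 124 kg N ha-1.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .data_core import EmissionRecord
from .model_suite import ModelSpec, ParamSet, mean_response

__all__ = [
    "DesignConfig",
    "TruthRecord",
    "default_world_design",
    "sample_doses",
    "generate_dataset",
]


@dataclass(frozen=True)
class DesignConfig:
    """Layout of a simulated multi-publication experiment.

    Doses are drawn independently per slot: 0 with probability
    ``zero_fraction`` (a control treatment), otherwise from a lognormal with
    the given log-mean/log-SD, truncated at ``max_dose`` by rejection.
    """

    n_publications: int = 203
    doses_per_publication: int | tuple[int, ...] = 3
    replicates_per_dose: int = 2
    zero_fraction: float = 1.0 / 3.0
    dose_log_mean: float = 5.08
    dose_log_sd: float = 0.70
    max_dose: float = 500.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_publications < 1:
            raise ValueError("need at least one publication")
        counts = self.dose_counts()
        if min(counts) < 1 or self.replicates_per_dose < 1:
            raise ValueError("dose and replicate counts must be >= 1")
        if not 0.0 <= self.zero_fraction <= 1.0:
            raise ValueError("zero_fraction must be a probability")
        if self.max_dose <= 0:
            raise ValueError("max_dose must be positive")

    def dose_counts(self) -> tuple[int, ...]:
        """Number of dose levels for each publication."""
        if isinstance(self.doses_per_publication, int):
            return (self.doses_per_publication,) * self.n_publications
        counts = tuple(self.doses_per_publication)
        if len(counts) != self.n_publications:
            raise ValueError("per-publication dose list has the wrong length")
        return counts


def default_world_design(seed: int = 0) -> DesignConfig:
    """World-scale default: 203 publications, 3 doses (one control on
    average) x 2 replicates, dose distribution calibrated so that large
    samples have median ~100 and mean ~124 kg N ha-1, max 500."""
    return DesignConfig(seed=seed)


def sample_doses(design: DesignConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` applied-N doses from the design's mixture sampler."""
    doses = np.zeros(n)
    positive = rng.random(n) >= design.zero_fraction
    n_pos = int(positive.sum())
    draws = np.empty(n_pos)
    filled = 0
    while filled < n_pos:
        cand = rng.lognormal(design.dose_log_mean, design.dose_log_sd, n_pos - filled)
        cand = cand[cand <= design.max_dose]
        draws[filled : filled + len(cand)] = cand
        filled += len(cand)
    doses[positive] = draws
    return doses


@dataclass
class TruthRecord:
    """Ground truth behind one simulated dataset.

    The realized per-publication effects are stored exactly as drawn so that
    oracle checks can condition on them.
    """

    spec: ModelSpec
    params: ParamSet
    alpha0: np.ndarray
    alpha1: np.ndarray
    seed: int

    def to_json(self, path: str | Path) -> None:
        payload = {
            "model": self.spec.name,
            "params": self.params.as_dict(),
            "alpha0": self.alpha0.tolist(),
            "alpha1": self.alpha1.tolist(),
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def generate_dataset(
    spec: ModelSpec,
    params: ParamSet,
    design: DesignConfig,
    seed: int | None = None,
) -> tuple[list[EmissionRecord], TruthRecord]:
    """Simulate a dataset from one model structure.

    Returns the records (grouped by synthetic publication ids ``pub0001``,
    ``pub0002``, ...) and the :class:`TruthRecord` holding the generating
    parameters and realized random effects.  Fully reproducible from the
    seed (``design.seed`` unless overridden).
    """
    params.validate_for(spec)
    used_seed = design.seed if seed is None else seed
    rng = np.random.default_rng(used_seed)
    P = design.n_publications

    alpha0 = (
        rng.normal(0.0, params.sigma0, P)
        if spec.random_intercept
        else np.zeros(P)
    )
    alpha1 = (
        rng.normal(0.0, params.sigma1, P) if spec.random_slope else np.zeros(P)
    )

    counts = design.dose_counts()
    records: list[EmissionRecord] = []
    for i in range(P):
        pub_id = f"pub{i + 1:04d}"
        doses = sample_doses(design, counts[i], rng)
        for j, dose in enumerate(doses):
            mean = mean_response(spec, params, float(dose), a0=alpha0[i], a1=alpha1[i])
            eps = rng.normal(0.0, params.tau, design.replicates_per_dose)
            for k in range(design.replicates_per_dose):
                records.append(
                    EmissionRecord(
                        publication_id=pub_id,
                        dose=float(dose),
                        n2o=float(mean + eps[k]),
                        replicate=k + 1,
                    )
                )
    truth = TruthRecord(spec=spec, params=params, alpha0=alpha0, alpha1=alpha1, seed=used_seed)
    return records, truth
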