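"""Uncertainty-distribution specifications used throughout the model.

Every uncertain model input carries a :class:`DistributionSpec` naming its
conjugate family (beta for binary probabilities, Dirichlet for categorical
shares, gamma for costs, ``fixed`` for settings held constant).  Base-case
values are the analytic means of these specifications, so a single object
serves both the deterministic and the probabilistic analyses.
"""

from __future__ import annotations

from typing import Literal

import numpy as np
from pydantic import BaseModel, model_validator
from scipy import stats

Family = Literal["beta", "dirichlet", "gamma", "fixed"]


class DistributionSpec(BaseModel):
    """A named parametric uncertainty distribution.

    params by family:
      beta      -- (a, b): pseudo-counts of events and non-events
      dirichlet -- per-category pseudo-counts (>= 2 categories)
      gamma     -- (mean, cv): mean on the natural scale and coefficient of
                   variation; parameterised so the sampling mean equals the
                   base value
      fixed     -- point mass, returned as-is (a single value, or a vector
                   for a degenerate categorical split)
    """

    family: Family
    params: tuple[float, ...]

    model_config = {"frozen": True}

    @model_validator(mode="after")
    def _check(self) -> "DistributionSpec":
        p = np.asarray(self.params, dtype=float)
        if p.size == 0 or not np.all(np.isfinite(p)):
            raise ValueError(f"{self.family}: params must be finite and non-empty")
        if self.family == "fixed":
            if np.any(p < 0):
                raise ValueError("fixed takes values >= 0")
        elif self.family == "beta":
            if p.size != 2 or np.any(p <= 0):
                raise ValueError("beta takes two strictly positive shape counts")
        elif self.family == "dirichlet":
            if p.size < 2 or np.any(p <= 0):
                raise ValueError("dirichlet takes >= 2 strictly positive counts")
        elif self.family == "gamma":
            if p.size != 2 or np.any(p <= 0):
                raise ValueError("gamma takes (mean, cv), both > 0")
        return self


def distribution_mean(spec: DistributionSpec) -> float | np.ndarray:
    """Analytic mean: beta a/(a+b); dirichlet counts/total; gamma its stated
    mean; fixed its value."""
    p = np.asarray(spec.params, dtype=float)
    if spec.family == "fixed":
        return float(p[0]) if p.size == 1 else p
    if spec.family == "beta":
        return float(p[0] / p.sum())
    if spec.family == "dirichlet":
        return p / p.sum()
    if spec.family == "gamma":
        return float(p[0])
    raise AssertionError(spec.family)


def sample_distribution(
    spec: DistributionSpec, rng: np.random.Generator
) -> float | np.ndarray:
    """One random draw from ``spec``; Dirichlet draws lie on the simplex."""
    p = np.asarray(spec.params, dtype=float)
    if spec.family == "fixed":
        return float(p[0]) if p.size == 1 else p
    if spec.family == "beta":
        x = float(rng.beta(p[0], p[1]))
    elif spec.family == "dirichlet":
        x = rng.dirichlet(p)
    elif spec.family == "gamma":
        mean, cv = p
        shape = 1.0 / cv**2
        x = float(rng.gamma(shape, mean / shape))
    else:  # pragma: no cover
        raise AssertionError(spec.family)
    if not np.all(np.isfinite(x)):
        raise ArithmeticError(f"non-finite draw from {spec}")
    return x


def quantile(spec: DistributionSpec, q: float) -> float | np.ndarray:
    """Marginal quantile (Dirichlet: per-category marginal Beta quantiles).

    Used for one-way (tornado) ranges, conventionally at q = 0.025 / 0.975.
    """
    p = np.asarray(spec.params, dtype=float)
    if spec.family == "fixed":
        return float(p[0]) if p.size == 1 else p
    if spec.family == "beta":
        return float(stats.beta.ppf(q, p[0], p[1]))
    if spec.family == "dirichlet":
        total = p.sum()
        return stats.beta.ppf(q, p, total - p)
    if spec.family == "gamma":
        mean, cv = p
        shape = 1.0 / cv**2
        return float(stats.gamma.ppf(q, shape, scale=mean / shape))
    raise AssertionError(spec.family)


def ppf(spec: DistributionSpec, u: float) -> float | np.ndarray:
    """Inverse-CDF transform of a shared uniform ``u`` (common random numbers)."""
    return quantile(spec, u)


def beta_from_mean_se(mean: float, se: float) -> DistributionSpec:
    """Moment-matched Beta for a probability with standard error ``se``.

    Degenerates to ``fixed`` when the variance is zero or incompatible with a
    Beta on (0, 1) (mean at the boundary).
    """
    if not 0.0 <= mean <= 1.0:
        raise ValueError("mean must lie in [0, 1]")
    var = se**2
    if var <= 0 or mean in (0.0, 1.0):
        return DistributionSpec(family="fixed", params=(mean,))
    nu = mean * (1.0 - mean) / var - 1.0
    if nu <= 0:
        raise ValueError("se too large for a Beta with this mean")
    return DistributionSpec(family="beta", params=(mean * nu, (1.0 - mean) * nu))
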