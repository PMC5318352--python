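"""Probabilistic parameters: distributions, Monte Carlo sampling, empirical CDFs.

Sampling is inverse-transform throughout: one stream of uniform [0, 1] draws
per parameter is generated once (seeded) and pushed through the analytic
quantile function. The propagation engine reuses the same stream across every
α-level and both membership-function passes, which makes the resulting CDF
families exactly nested instead of Monte Carlo jittered.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
from scipy import stats

__all__ = [
    "DistributionSpec",
    "SampleSet",
    "EmpiricalCDF",
    "sample",
    "ecdf",
    "quantile",
]


@dataclass(frozen=True)
class DistributionSpec:
    """A probabilistic model parameter: Normal(mean, sd) or a constant.

    Constants flow through the probabilistic path so mixed models need no
    special-casing; their "quantile" is the value itself.
    """

    family: str  # "normal" | "constant"
    mean: float = 0.0
    sd: float = 0.0
    value: float = 0.0

    @classmethod
    def normal(cls, mean: float, sd: float) -> "DistributionSpec":
        if not sd > 0:
            raise ValueError(f"normal distribution requires sd > 0, got {sd}")
        return cls(family="normal", mean=float(mean), sd=float(sd))

    @classmethod
    def constant(cls, value: float) -> "DistributionSpec":
        return cls(family="constant", value=float(value))

    def validate(self) -> list[str]:
        if self.family == "normal":
            return [] if self.sd > 0 else [f"normal sd must be > 0, got {self.sd}"]
        if self.family == "constant":
            return [] if np.isfinite(self.value) else [f"constant value not finite: {self.value}"]
        return [f"unsupported distribution family {self.family!r}"]

    def ppf(self, u):
        """Quantile function applied to uniform draw(s) ``u`` (inverse transform)."""
        if self.family == "normal":
            return stats.norm.ppf(u, loc=self.mean, scale=self.sd)
        if self.family == "constant":
            return np.full_like(np.asarray(u, dtype=float), self.value)
        raise ValueError(f"unsupported distribution family {self.family!r}")

    def to_dict(self) -> dict:
        if self.family == "normal":
            return {"dist": "normal", "mean": self.mean, "sd": self.sd}
        return {"dist": "constant", "value": self.value}

    @classmethod
    def from_dict(cls, d: dict) -> "DistributionSpec":
        family = d.get("dist")
        if family == "normal":
            return cls.normal(d["mean"], d["sd"])
        if family == "constant":
            return cls.constant(d["value"])
        raise ValueError(f"unsupported distribution family {family!r}")


@dataclass(frozen=True)
class SampleSet:
    """Monte Carlo draws of one parameter, tagged with the seed that made them."""

    values: np.ndarray
    seed: int

    @property
    def n(self) -> int:
        return self.values.size

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.size < 1:
            raise ValueError("sample set must hold at least one draw")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("sample set contains non-finite values")


def sample(spec: DistributionSpec, n: int, seed: int) -> SampleSet:
    """Draw ``n`` values by inverse-transform sampling of seeded uniforms."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    violations = spec.validate()
    if violations:
        raise ValueError("; ".join(violations))
    rng = np.random.default_rng(seed)
    u = rng.uniform(size=n)
    return SampleSet(values=spec.ppf(u), seed=seed)


class EmpiricalCDF:
    """Right-continuous step CDF of a sample: F(x) = #{x_i <= x} / n.

    Quantiles use the type-1 generalized inverse inf{x : F(x) >= p},
    i.e. the ceil(p·n)-th order statistic.
    """

    convention = "type-1 generalized inverse"

    def __init__(self, values) -> None:
        values = np.asarray(values, dtype=float)
        if values.size == 0:
            raise ValueError("cannot build an empirical CDF from an empty sample")
        if not np.all(np.isfinite(values)):
            raise ValueError("empirical CDF input contains non-finite values")
        self.values = np.sort(values)
        self.n = self.values.size

    def __call__(self, x):
        return np.searchsorted(self.values, x, side="right") / self.n

    def quantile(self, p):
        p = np.asarray(p, dtype=float)
        if np.any(p <= 0) or np.any(p >= 1):
            raise ValueError("quantile probability must lie in (0, 1)")
        idx = np.ceil(p * self.n).astype(int) - 1
        out = self.values[np.clip(idx, 0, self.n - 1)]
        return float(out) if out.ndim == 0 else out

    def to_frame(self):
        """Two-column export (value, cumulative probability)."""
        import pandas as pd

        return pd.DataFrame(
            {"value": self.values, "cum_prob": np.arange(1, self.n + 1) / self.n}
        )


def ecdf(samples: Union[SampleSet, np.ndarray]) -> EmpiricalCDF:
    """Empirical CDF of a sample set (or bare array of draws)."""
    values = samples.values if isinstance(samples, SampleSet) else samples
    return EmpiricalCDF(values)


def quantile(F: Union[EmpiricalCDF, DistributionSpec], p: float):
    """p-quantile of an empirical CDF or the analytic quantile of a spec."""
    if isinstance(F, EmpiricalCDF):
        return F.quantile(p)
    if isinstance(F, DistributionSpec):
        if np.any(np.asarray(p) <= 0) or np.any(np.asarray(p) >= 1):
            raise ValueError("quantile probability must lie in (0, 1)")
        if F.family == "constant":
            return F.value
        out = F.ppf(p)
        return float(out) if np.ndim(out) == 0 else out
    raise TypeError(f"cannot take quantiles of {type(F).__name__}")
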