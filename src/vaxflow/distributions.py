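"""Shifted parametric service-time distributions.

Service times at every station are modelled as ``shift + X`` where ``shift``
is a fixed minimum service time in minutes and ``X`` is a draw from one of
five parametric families (exponential, normal, log-normal, gamma, Weibull).
The shift captures the irreducible part of a task — no registration takes
less than, say, 3 minutes — while the parametric tail captures the minority
of patients who take much longer.  A sixth family, ``uniform``, is supported
for modelling short serverless delays such as walking between stations.

The post-vaccination observation stay is bimodal: a tight normal for the
large majority of patients, and a shifted exponential with a long tail for
the small fraction (2% by default) who experience an adverse reaction and
must be observed for longer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import stats

__all__ = [
    "ConfigurationError",
    "DistributionSpec",
    "ObservationMixtureSpec",
    "sample_service_times",
    "quantile",
    "sample_observation",
]

FAMILIES = ("exponential", "normal", "lognormal", "gamma", "weibull", "uniform")

#: parameter names accepted per family, in canonical order
_FAMILY_PARAMS = {
    "exponential": ("rate",),
    "normal": ("mean", "sd"),
    "lognormal": ("logmean", "logsd"),
    "gamma": ("shape", "rate"),
    "weibull": ("shape", "scale"),
    "uniform": ("low", "high"),
}


class ConfigurationError(ValueError):
    """Raised when a distribution or scenario is mis-specified."""


@dataclass(frozen=True)
class DistributionSpec:
    """A service-time distribution: ``shift`` minutes plus a parametric draw.

    Parameters
    ----------
    family:
        One of ``exponential``, ``normal``, ``lognormal``, ``gamma``,
        ``weibull`` or ``uniform``.
    shift:
        Fixed minimum service time in minutes (>= 0).  Added to every draw.
        For the normal family the shift is conventionally 0 and negative
        draws are resampled, since a service time cannot be negative.
    params:
        Family-specific parameters:
        exponential ``rate``; normal ``mean, sd``; lognormal
        ``logmean, logsd``; gamma ``shape, rate``; weibull ``shape, scale``;
        uniform ``low, high``.
    """

    family: str
    shift: float = 0.0
    params: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ConfigurationError(
                f"unknown distribution family {self.family!r}; "
                f"expected one of {', '.join(FAMILIES)}"
            )
        if self.shift < 0:
            raise ConfigurationError(f"shift must be >= 0, got {self.shift}")
        expected = _FAMILY_PARAMS[self.family]
        unknown = set(self.params) - set(expected)
        if unknown:
            raise ConfigurationError(
                f"unexpected parameter(s) {sorted(unknown)} for family "
                f"{self.family!r}; expected {list(expected)}"
            )
        missing = set(expected) - set(self.params)
        if missing:
            raise ConfigurationError(
                f"missing parameter(s) {sorted(missing)} for family {self.family!r}"
            )
        p = self.params
        if self.family == "exponential" and p["rate"] <= 0:
            raise ConfigurationError(f"rate must be > 0, got {p['rate']}")
        if self.family == "normal" and p["sd"] <= 0:
            raise ConfigurationError(f"sd must be > 0, got {p['sd']}")
        if self.family == "lognormal" and p["logsd"] <= 0:
            raise ConfigurationError(f"logsd must be > 0, got {p['logsd']}")
        if self.family == "gamma" and (p["shape"] <= 0 or p["rate"] <= 0):
            raise ConfigurationError("gamma shape and rate must be > 0")
        if self.family == "weibull" and (p["shape"] <= 0 or p["scale"] <= 0):
            raise ConfigurationError("weibull shape and scale must be > 0")
        if self.family == "uniform" and not (0 <= p["low"] <= p["high"]):
            raise ConfigurationError("uniform requires 0 <= low <= high")

    # -- scipy plumbing ----------------------------------------------------

    def _frozen(self):
        """The unshifted base distribution as a frozen scipy object."""
        p = self.params
        if self.family == "exponential":
            return stats.expon(scale=1.0 / p["rate"])
        if self.family == "normal":
            return stats.norm(loc=p["mean"], scale=p["sd"])
        if self.family == "lognormal":
            return stats.lognorm(s=p["logsd"], scale=float(np.exp(p["logmean"])))
        if self.family == "gamma":
            return stats.gamma(p["shape"], scale=1.0 / p["rate"])
        if self.family == "weibull":
            return stats.weibull_min(p["shape"], scale=p["scale"])
        return stats.uniform(loc=p["low"], scale=p["high"] - p["low"])

    @property
    def mean(self) -> float:
        """Expected value in minutes, including the shift."""
        return self.shift + float(self._frozen().mean())

    def to_config(self) -> dict[str, Any]:
        """Serialise as a flat mapping, e.g. ``{family, shift, rate}``."""
        out: dict[str, Any] = {"family": self.family, "shift": self.shift}
        out.update(self.params)
        return out

    @classmethod
    def from_config(cls, cfg: dict[str, Any]) -> "DistributionSpec":
        cfg = dict(cfg)
        family = cfg.pop("family", None)
        if family is None:
            raise ConfigurationError("distribution spec is missing 'family'")
        shift = cfg.pop("shift", 0.0)
        return cls(family=family, shift=float(shift), params={k: float(v) for k, v in cfg.items()})


# convenience constructors used throughout the network presets
def shifted_exponential(shift: float, rate: float) -> DistributionSpec:
    return DistributionSpec("exponential", shift, {"rate": rate})


def normal(mean: float, sd: float) -> DistributionSpec:
    return DistributionSpec("normal", 0.0, {"mean": mean, "sd": sd})


def uniform(low: float, high: float) -> DistributionSpec:
    return DistributionSpec("uniform", 0.0, {"low": low, "high": high})


@dataclass(frozen=True)
class ObservationMixtureSpec:
    """Bimodal observation-stay distribution.

    ``main`` applies to the majority of patients; ``adverse`` (a shifted
    exponential with a heavy tail) applies to the random ``adverse_prob``
    fraction who have an adverse reaction after vaccination.
    """

    main: DistributionSpec
    adverse: DistributionSpec
    adverse_prob: float = 0.02

    def __post_init__(self) -> None:
        if not 0.0 <= self.adverse_prob <= 1.0:
            raise ConfigurationError(
                f"adverse_prob must be in [0, 1], got {self.adverse_prob}"
            )

    @property
    def mean(self) -> float:
        return (1 - self.adverse_prob) * self.main.mean + self.adverse_prob * self.adverse.mean

    def to_config(self) -> dict[str, Any]:
        return {
            "main": self.main.to_config(),
            "adverse": self.adverse.to_config(),
            "adverse_prob": self.adverse_prob,
        }

    @classmethod
    def from_config(cls, cfg: dict[str, Any]) -> "ObservationMixtureSpec":
        return cls(
            main=DistributionSpec.from_config(cfg["main"]),
            adverse=DistributionSpec.from_config(cfg["adverse"]),
            adverse_prob=float(cfg.get("adverse_prob", 0.02)),
        )


def sample_service_times(
    spec: DistributionSpec, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` service times (minutes) from a shifted distribution.

    All values are >= ``spec.shift`` for families whose base support is
    non-negative.  Normal draws that come out negative are resampled, so
    service times are never negative; with the narrow normals used for
    observation stays this essentially never triggers.
    """
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    draws = np.asarray(spec._frozen().rvs(size=n, random_state=rng), dtype=float)
    if spec.family == "normal":
        bad = draws < 0
        while bad.any():
            draws[bad] = spec._frozen().rvs(size=int(bad.sum()), random_state=rng)
            bad = draws < 0
    return spec.shift + draws


def quantile(spec: DistributionSpec, p) -> float | np.ndarray:
    """Closed-form quantile ``shift + F^{-1}(p)`` of a shifted distribution.

    ``p`` must lie strictly inside (0, 1); scalars and arrays are accepted.
    """
    p_arr = np.asarray(p, dtype=float)
    if np.any(p_arr <= 0) or np.any(p_arr >= 1):
        raise ValueError(f"p must be in the open interval (0, 1), got {p!r}")
    q = spec.shift + spec._frozen().ppf(p_arr)
    return float(q) if np.isscalar(p) or p_arr.ndim == 0 else q


def sample_observation(
    mix: ObservationMixtureSpec, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` observation stays and their adverse-reaction flags.

    Each patient independently has an adverse reaction with probability
    ``mix.adverse_prob``; their stay is drawn from the component matching
    the flag.  Returns ``(durations, adverse_flags)``.
    """
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    adverse = rng.random(n) < mix.adverse_prob
    durations = np.empty(n, dtype=float)
    n_main = int((~adverse).sum())
    durations[~adverse] = sample_service_times(mix.main, n_main, rng)
    durations[adverse] = sample_service_times(mix.adverse, n - n_main, rng)
    return durations, adverse
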