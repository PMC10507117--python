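"""Species-level model parameters and their sampling distributions.

Every colonizing species receives its own draw of each demographic
parameter from a uniform distribution specified by a mean and a variance.
A uniform with mean ``m`` and variance ``v`` has support
``[m - sqrt(3 v), m + sqrt(3 v)]``, which matches the stated moments
exactly.  Parameters that must be positive are truncated at zero.

The shipped default means and variances are configurable assumptions:
they follow the published parameterizations of the underlying
consumer-resource pollination model, with interspecific plant competition
strengthened (higher mean/variance of rewards production ``beta``, pollen
pickup ``epsilon`` and interspecific competition ``u``; lower intraspecific
competition ``w``; wider visitation-efficiency ``tau`` spread) so that
assembly exhibits species turnover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "Moments",
    "PlantParams",
    "PollinatorParams",
    "ParamDistributions",
    "uniform_from_moments",
    "default_distributions",
]


@dataclass(frozen=True)
class Moments:
    """Mean/variance pair defining a uniform sampling distribution."""

    mean: float
    var: float = 0.0

    def bounds(self) -> tuple[float, float]:
        h = math.sqrt(3.0 * self.var)
        return self.mean - h, self.mean + h


def uniform_from_moments(
    moments: Moments,
    rng: np.random.Generator,
    size: int | None = None,
    truncate_at_zero: bool = True,
):
    """Draw from the uniform distribution with the given mean and variance.

    With ``truncate_at_zero`` the lower bound is clipped at zero, which
    slightly shifts the realized moments when ``sqrt(3 v) > m``; a
    negative lower bound without truncation raises ``ValueError`` for
    positivity-constrained parameters.
    """
    lo, hi = moments.bounds()
    if lo < 0.0:
        if not truncate_at_zero:
            raise ValueError(
                f"uniform(mean={moments.mean}, var={moments.var}) has negative "
                f"lower bound {lo:.4g}; enable truncation or reduce variance"
            )
        lo = 0.0
    if moments.var == 0.0:
        return moments.mean if size is None else np.full(size, moments.mean)
    return rng.uniform(lo, hi, size=size)


@dataclass
class PlantParams:
    """Demographic parameters of one plant species.

    g        max fraction of seeds recruiting to adults (dimensionless, <= 1)
    u        interspecific competition for non-mutualistic resources
    w        intraspecific competition for non-mutualistic resources
    beta     floral rewards production rate (rewards per abundance per time)
    phi      rewards saturation (self-limitation) rate (per time)
    eps      pollen picked up per visit (dimensionless weight)
    mu_P     plant mortality rate (per time)
    e        expected seeds per pollination event
    """

    g: float
    u: float
    w: float
    beta: float
    phi: float
    eps: float
    mu_P: float
    e: float

    def __post_init__(self) -> None:
        for name in ("g", "beta", "phi", "eps", "mu_P", "e"):
            if getattr(self, name) <= 0:
                raise ValueError(f"plant parameter {name} must be positive")
        if self.u < 0 or self.w < 0:
            raise ValueError("competition coefficients u, w must be nonnegative")
        if self.g > 1:
            raise ValueError("recruitment fraction g cannot exceed 1")


@dataclass
class PollinatorParams:
    """Demographic parameters of one pollinator species.

    tau      visitation efficiency (per plant-abundance per time)
    c        rewards-to-births conversion efficiency
    b        rewards extraction efficiency per visit
    mu_A     pollinator mortality rate (per time)
    G        adaptive foraging rate (per time); G = 0 is a fixed forager
    """

    tau: float
    c: float
    b: float
    mu_A: float
    G: float

    def __post_init__(self) -> None:
        for name in ("tau", "c", "b", "mu_A"):
            if getattr(self, name) <= 0:
                raise ValueError(f"pollinator parameter {name} must be positive")
        if self.G < 0:
            raise ValueError("adaptive foraging rate G must be nonnegative")


_PLANT_FIELDS = ("g", "u", "w", "beta", "phi", "eps", "mu_P", "e")
_POLL_FIELDS = ("tau", "c", "b", "mu_A", "G")

# g <= 1 additionally enforced by clipping the draw.
_NONNEG_ONLY = {"u", "w", "G"}


@dataclass
class ParamDistributions:
    """Per-parameter (mean, variance) pairs for both guilds."""

    plant: dict[str, Moments] = field(default_factory=dict)
    pollinator: dict[str, Moments] = field(default_factory=dict)

    def sample_plant(self, rng: np.random.Generator) -> PlantParams:
        draws = {k: float(uniform_from_moments(m, rng)) for k, m in self.plant.items()}
        draws["g"] = min(draws["g"], 1.0)
        for k, v in draws.items():
            if k not in _NONNEG_ONLY:
                draws[k] = max(v, 1e-12)
        return PlantParams(**draws)

    def sample_pollinator(self, rng: np.random.Generator) -> PollinatorParams:
        draws = {k: float(uniform_from_moments(m, rng)) for k, m in self.pollinator.items()}
        for k, v in draws.items():
            if k not in _NONNEG_ONLY:
                draws[k] = max(v, 1e-12)
        return PollinatorParams(**draws)

    def to_dict(self) -> dict:
        return {
            "plant": {k: asdict(m) for k, m in self.plant.items()},
            "pollinator": {k: asdict(m) for k, m in self.pollinator.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ParamDistributions":
        def load(sub: dict) -> dict[str, Moments]:
            return {k: Moments(**v) for k, v in sub.items()}

        return cls(plant=load(d.get("plant", {})), pollinator=load(d.get("pollinator", {})))


def default_distributions() -> ParamDistributions:
    """Default parameter distributions (means and variances).

    Pollinator mortality is fixed at 0.001 per timestep, which sets the
    population doubling time to ln(2)/0.001 ~ 693 timesteps (one
    generation).  The adaptive foraging rate G is a point mass; the
    fixed-forager model variant overrides it to zero.
    """
    hw = lambda m, h: Moments(m, h * h / 3.0)  # mean + half-width
    return ParamDistributions(
        plant={
            "g": hw(0.4, 0.1),
            "u": hw(0.12, 0.06),
            "w": hw(0.3, 0.1),
            "beta": hw(0.4, 0.2),
            "phi": hw(0.04, 0.01),
            "eps": hw(1.0, 0.4),
            "mu_P": hw(0.014, 0.007),
            "e": hw(0.8, 0.2),
        },
        pollinator={
            "tau": hw(1.0, 0.8),
            "c": hw(0.2, 0.05),
            "b": hw(0.4, 0.3),
            "mu_A": Moments(0.001, 0.0),
            "G": Moments(30.0, 0.0),
        },
    )
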