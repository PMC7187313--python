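"""Prior set for the lynx state-space model, with beta moment matching.

Informative priors come from long-term radio-telemetry studies: survival
(phi1, phi2), recruitment (r1, r2 per geographical area), and the
family-groups-per-female conversion (F, sigma_F).  Vague priors are used
for the additional mortality rho (uniform on [0,1]), the process error
sigma_p (uniform on [0,4]), and the initial stage composition psi
(a weakly informative Dirichlet).

Geographical areas: 1 = northern Sweden, 2 = southern Norway,
3 = northern Norway.  Recruitment priors are shared between areas 1 and 3
(reindeer husbandry areas) and distinct for area 2 (roe-deer range, with
higher recruitment).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import yaml

__all__ = [
    "BetaSpec",
    "UniformSpec",
    "NormalSpec",
    "PriorSet",
    "beta_from_moments",
    "beta_moments",
    "default_prior_set",
]


class InfeasibleMomentsError(ValueError):
    """No beta distribution has the requested mean/sd pair."""


@dataclass(frozen=True)
class BetaSpec:
    """Shape parameters of a beta distribution."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0):
            raise ValueError("beta shapes must be strictly positive")


@dataclass(frozen=True)
class UniformSpec:
    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.high > self.low:
            raise ValueError("uniform bounds must satisfy high > low")


@dataclass(frozen=True)
class NormalSpec:
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise ValueError("normal sd must be positive")


def beta_from_moments(mean: float, sd: float) -> BetaSpec:
    """Beta shapes matching a given mean and standard deviation.

    Uses ``alpha = mean * c``, ``beta = (1 - mean) * c`` with
    ``c = mean * (1 - mean) / sd**2 - 1``.  Raises
    :class:`InfeasibleMomentsError` when ``sd**2 >= mean * (1 - mean)``,
    where no beta distribution exists.
    """
    if not 0.0 < mean < 1.0:
        raise InfeasibleMomentsError(f"mean={mean} must lie in (0, 1)")
    var = sd * sd
    if var >= mean * (1.0 - mean):
        raise InfeasibleMomentsError(
            f"sd={sd} too large for mean={mean}: sd^2 must be < mean*(1-mean)"
        )
    c = mean * (1.0 - mean) / var - 1.0
    return BetaSpec(alpha=mean * c, beta=(1.0 - mean) * c)


def beta_moments(spec: BetaSpec) -> tuple[float, float]:
    """Mean and standard deviation of a beta distribution."""
    a, b = spec.alpha, spec.beta
    s = a + b
    mean = a / s
    sd = math.sqrt(a * b / (s * s * (s + 1.0)))
    return mean, sd


@dataclass(frozen=True)
class PriorSet:
    """The full prior configuration of the state-space model.

    Per-area entries are 3-tuples indexed by geographical area (1, 2, 3).
    ``psi`` holds Dirichlet concentrations for the initial stage
    composition; ``b`` and ``sigma_q`` parameterize the quota decision
    regression priors.
    """

    phi1: BetaSpec
    phi2: BetaSpec
    r1: tuple[BetaSpec, BetaSpec, BetaSpec]
    r2: tuple[BetaSpec, BetaSpec, BetaSpec]
    F: tuple[BetaSpec, BetaSpec, BetaSpec]
    sigma_F: tuple[BetaSpec, BetaSpec, BetaSpec]
    rho: UniformSpec = field(default_factory=lambda: UniformSpec(0.0, 1.0))
    sigma_p: UniformSpec = field(default_factory=lambda: UniformSpec(0.0, 4.0))
    psi: tuple[float, float, float] = (3.15, 2.48, 9.16)
    b: NormalSpec = field(default_factory=lambda: NormalSpec(0.0, 3000.0))
    sigma_q: UniformSpec = field(default_factory=lambda: UniformSpec(0.0, 4.0))

    def relax(self, name: str, area: int | None = None) -> "PriorSet":
        """Replace one informative beta prior with uniform(0, 1) = beta(1, 1).

        Used by the prior-sensitivity procedure: one demographic parameter
        at a time is made vague and the effect on the growth rate observed.
        ``area`` (1-3) selects the entry for per-area parameters.
        """
        flat = BetaSpec(1.0, 1.0)
        if name in ("phi1", "phi2"):
            return replace(self, **{name: flat})
        if name in ("r1", "r2", "F", "sigma_F"):
            if area is None:
                raise ValueError(f"{name} is per-area; pass area in {{1,2,3}}")
            current = list(getattr(self, name))
            current[area - 1] = flat
            return replace(self, **{name: tuple(current)})
        if name == "rho":
            return self  # already uniform(0, 1): relaxation is a no-op
        raise ValueError(f"cannot relax prior {name!r}")

    def inflate_sigma_F(self, factor: float = 1.3) -> "PriorSet":
        """Scale every area's sigma_F prior mean by ``factor``.

        Realizes the observation-ratio sensitivity check (a 30 percent
        larger sd of family groups per female).
        """
        new = []
        for spec in self.sigma_F:
            mean, sd = beta_moments(spec)
            new.append(beta_from_moments(min(mean * factor, 0.999), sd))
        return replace(self, sigma_F=tuple(new))

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        def enc(spec):
            if isinstance(spec, BetaSpec):
                return {"beta": [spec.alpha, spec.beta]}
            if isinstance(spec, UniformSpec):
                return {"uniform": [spec.low, spec.high]}
            if isinstance(spec, NormalSpec):
                return {"normal": [spec.mean, spec.sd]}
            raise TypeError(type(spec))

        return {
            "phi1": enc(self.phi1),
            "phi2": enc(self.phi2),
            "r1": [enc(s) for s in self.r1],
            "r2": [enc(s) for s in self.r2],
            "F": [enc(s) for s in self.F],
            "sigma_F": [enc(s) for s in self.sigma_F],
            "rho": enc(self.rho),
            "sigma_p": enc(self.sigma_p),
            "psi": list(self.psi),
            "b": enc(self.b),
            "sigma_q": enc(self.sigma_q),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PriorSet":
        def dec(obj):
            (family, params), = obj.items()
            if family == "beta":
                return BetaSpec(*params)
            if family == "uniform":
                return UniformSpec(*params)
            if family == "normal":
                return NormalSpec(*params)
            raise ValueError(f"unknown prior family {family!r}")

        return cls(
            phi1=dec(d["phi1"]),
            phi2=dec(d["phi2"]),
            r1=tuple(dec(s) for s in d["r1"]),
            r2=tuple(dec(s) for s in d["r2"]),
            F=tuple(dec(s) for s in d["F"]),
            sigma_F=tuple(dec(s) for s in d["sigma_F"]),
            rho=dec(d["rho"]),
            sigma_p=dec(d["sigma_p"]),
            psi=tuple(d["psi"]),
            b=dec(d["b"]),
            sigma_q=dec(d["sigma_q"]),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PriorSet":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_prior_set() -> PriorSet:
    """The standard prior configuration of the lynx model.

    Note the published beta(4, 14) recruitment prior for areas 1 and 3 is
    quoted with mean 0.19, while the shapes imply 4/18 = 0.222; the shape
    parameters are taken as authoritative here.
    """
    r13_1 = BetaSpec(4.0, 14.0)
    r13_2 = BetaSpec(55.0, 85.0)
    F = BetaSpec(126.0, 278.0)
    sigF = BetaSpec(20.7, 877.0)
    return PriorSet(
        phi1=BetaSpec(9.1, 1.01),
        phi2=BetaSpec(20.5, 0.74),
        r1=(r13_1, BetaSpec(9.0, 9.0), r13_1),
        r2=(r13_2, BetaSpec(53.0, 53.0), r13_2),
        F=(F, F, F),
        sigma_F=(sigF, sigF, sigF),
    )
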