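"""Deterministic stage-structured core of the lynx population model.

The female-only life cycle has three stages at the pre-breeding (February)
census: kittens aged 9 months, subadults aged 21 months, and adults aged
33 months and older.  Births occur as a June pulse; the legal quota harvest
is a March pulse immediately after the census, so harvest is removed from
the state vector *before* projection.

Survival enters at fractional-year powers because events are spaced within
the census year: mothers must survive one quarter year from census to the
birth pulse (``phi2 ** (1/4)``), while the latent "additional" mortality
``rho`` (poaching and other mortality unseen by telemetry) acts on average
at mid-interval (``phi ** (1/2)`` annually, ``phi ** (1/8)`` for the
census-to-birth quarter).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = [
    "VitalRates",
    "STAGE_NAMES",
    "STATE_FLOOR",
    "build_projection_matrix",
    "derived_survival",
    "potential_growth_rate",
    "stable_age_distribution",
    "project",
]

logger = logging.getLogger(__name__)

STAGE_NAMES = ("kitten", "subadult", "adult")

#: Floor applied to post-harvest states so the lognormal process model stays
#: defined when the recorded harvest exceeds a latent state.
STATE_FLOOR = 1e-6


class InvalidParameterError(ValueError):
    """A vital-rate combination implies a negative projection-matrix entry."""


@dataclass(frozen=True)
class VitalRates:
    """Vital rates for one geographical area (harvest mortality excluded).

    Parameters
    ----------
    phi1
        Annual survival probability of subadult females (9 -> 21 months).
    phi2
        Annual survival probability of females aged 21 months and older.
    r1
        Female kittens surviving to their first census per 2-yr-old female.
    r2
        Female kittens surviving to first census per female aged >= 3 yr.
    rho
        Additional annual mortality probability acting on yearlings and
        adults beyond ``phi`` and the recorded legal harvest.
    """

    phi1: float
    phi2: float
    r1: float
    r2: float
    rho: float

    def __post_init__(self) -> None:
        for name in ("phi1", "phi2", "r1", "r2", "rho"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise InvalidParameterError(f"{name}={value!r} outside [0, 1]")
        # derived survivals must stay nonnegative; checked again entry-wise
        # in build_projection_matrix with a more specific message
        for name, phi in (("phi1", self.phi1), ("phi2", self.phi2)):
            if derived_survival(phi, self.rho, _validate=False) < 0.0:
                raise InvalidParameterError(
                    f"derived survival {name} - rho*sqrt({name}) < 0 "
                    f"for {name}={phi}, rho={self.rho}"
                )


def derived_survival(phi: float, rho: float, *, _validate: bool = True) -> float:
    """Effective annual survival ``phi - rho * phi**0.5``.

    ``rho`` acts at mid-year on animals that would otherwise have survived
    half the year, so the additional deaths are ``rho * phi**0.5``.
    """
    phi = float(phi)
    rho = float(rho)
    if _validate:
        if not (0.0 <= phi <= 1.0 and 0.0 <= rho <= 1.0):
            raise InvalidParameterError("phi and rho must lie in [0, 1]")
    out = phi - rho * np.sqrt(phi)
    if _validate and out < 0.0:
        raise InvalidParameterError(
            f"derived survival negative for phi={phi}, rho={rho}"
        )
    return float(out)


def build_projection_matrix(v: VitalRates) -> np.ndarray:
    """Pre-breeding projection matrix ``A`` (3x3) for one area.

    Fecundity terms carry the mother's survival from census to the birth
    pulse, reduced by the additional mortality:
    ``a12 = r1 * (phi2**0.25 - rho * phi2**0.125)`` and likewise ``a13``
    with ``r2``.  Transition terms are the derived annual survivals.
    Entries (0,0), (1,1), (1,2), (2,0) are structurally zero.
    """
    season_surv = v.phi2**0.25 - v.rho * v.phi2**0.125
    a12 = v.r1 * season_surv
    a13 = v.r2 * season_surv
    a21 = derived_survival(v.phi1, v.rho, _validate=False)
    a32 = derived_survival(v.phi2, v.rho, _validate=False)
    entries = {"a12": a12, "a13": a13, "a21": a21, "a32": a32, "a33": a32}
    for name, value in entries.items():
        if value < 0.0:
            raise InvalidParameterError(
                f"projection-matrix entry {name}={value:.6g} is negative "
                f"for {v!r}"
            )
    return np.array(
        [
            [0.0, a12, a13],
            [a21, 0.0, 0.0],
            [0.0, a32, a32],
        ]
    )


def potential_growth_rate(A: np.ndarray) -> float:
    """Dominant eigenvalue of ``A`` -- the potential growth rate ``lambda``.

    For a nonnegative matrix the dominant eigenvalue is real by
    Perron-Frobenius; the imaginary part of the returned root is asserted
    negligible.
    """
    A = np.asarray(A, dtype=float)
    eigvals = np.linalg.eigvals(A)
    idx = int(np.argmax(np.abs(eigvals)))
    lam = eigvals[idx]
    if abs(lam.imag) >= 1e-10:
        raise ValueError(f"dominant eigenvalue not real: {lam!r}")
    return float(max(lam.real, 0.0))


def stable_age_distribution(A: np.ndarray) -> np.ndarray:
    """Normalized dominant right eigenvector: stable stage proportions."""
    A = np.asarray(A, dtype=float)
    eigvals, eigvecs = np.linalg.eig(A)
    idx = int(np.argmax(np.abs(eigvals)))
    vec = np.real(eigvecs[:, idx])
    vec = np.abs(vec)
    total = vec.sum()
    if total <= 0.0:
        raise ValueError("degenerate dominant eigenvector")
    return vec / total


def project(
    n: np.ndarray, h: np.ndarray, A: np.ndarray, *, floor: float = STATE_FLOOR
) -> np.ndarray:
    """One deterministic census-to-census step: ``mu = A @ max(n - h, floor)``.

    The harvest pulse follows the census immediately, so ``h`` is removed
    before projecting.  Post-harvest states that would go nonpositive are
    floored at ``floor`` (over-harvest of a latent state), with a warning.
    """
    n = np.asarray(n, dtype=float)
    h = np.asarray(h, dtype=float)
    if np.any(n < 0) or np.any(h < 0):
        raise ValueError("states and harvests must be nonnegative")
    remaining = n - h
    if np.any(remaining < floor):
        logger.warning(
            "harvest meets or exceeds a latent state; flooring %d entries at %g",
            int(np.sum(remaining < floor)),
            floor,
        )
        remaining = np.maximum(remaining, floor)
    return np.asarray(A, dtype=float) @ remaining
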