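"""Poisson-threshold cell survival model and goodness-of-fit statistic.

The model treats radiation damage as a Poisson process: a dose ``D`` (Gy)
produces ``n`` "unit damages" with probability ``P(n) = (alpha*D)^n / n! *
exp(-alpha*D)``, where ``alpha`` is the mean number of unit damages per Gy.
A cell carrying ``n`` damages repairs them all and survives with
probability ``beta**n``; above a threshold of ``m`` damages the injury is
unrepairable.  The surviving fraction is therefore the truncated series

    SF(D) = exp(-alpha*D) * sum_{n=0}^{m} (beta*alpha*D)^n / n!

Limits: ``m = 0`` gives pure exponential killing ``exp(-alpha*D)``;
``m -> inf`` gives ``exp(-alpha*(1-beta)*D)``; ``beta = 1`` gives the
cumulative Poisson probability ``P(N <= m)`` at mean ``alpha*D``.  The
classical linear-quadratic (LQ) model is provided as a comparator.

Fit quality is scored with the root-mean-square percentage error (RMSPE),
appropriate for survival fractions spanning three orders of magnitude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DomainError",
    "SurvivalPoint",
    "SurvivalDataset",
    "PoissonSurvivalParams",
    "LQParams",
    "eval_sf_poisson",
    "eval_sf_lq",
    "rmspe",
]

BEAM_TYPES = ("pristine", "sobp", "photon")
RADIATIONS = ("proton", "photon")


class DomainError(ValueError):
    """Raised when an input lies outside the model's mathematical domain."""


@dataclass(frozen=True)
class SurvivalPoint:
    """One clonogenic measurement: absorbed dose (Gy) and surviving fraction.

    Surviving fractions are log-scale data and must be strictly positive;
    a zero surviving fraction cannot be fitted and is rejected.
    """

    dose: float
    sf_observed: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.dose) and self.dose >= 0):
            raise DomainError(f"dose must be finite and >= 0, got {self.dose}")
        if not (math.isfinite(self.sf_observed) and self.sf_observed > 0):
            raise DomainError(
                f"surviving fraction must be finite and > 0, got {self.sf_observed}"
            )


@dataclass
class SurvivalDataset:
    """One survival curve: a cell line irradiated at a single nominal LET.

    ``let_kev_um`` is the dose-averaged LET in keV/µm (0 for photon
    reference curves).  Zero-dose points may be stored but are excluded
    from fitting (``fit_points``).
    """

    cell_line: str
    publication: str
    beam_type: str
    radiation: str
    let_kev_um: float
    points: list[SurvivalPoint]

    def __post_init__(self) -> None:
        if self.beam_type not in BEAM_TYPES:
            raise DomainError(f"beam_type must be one of {BEAM_TYPES}, got {self.beam_type!r}")
        if self.radiation not in RADIATIONS:
            raise DomainError(f"radiation must be one of {RADIATIONS}, got {self.radiation!r}")
        if self.radiation == "photon" and self.beam_type != "photon":
            raise DomainError("photon radiation requires beam_type='photon'")
        if not (math.isfinite(self.let_kev_um) and self.let_kev_um >= 0):
            raise DomainError(f"LET must be finite and >= 0, got {self.let_kev_um}")
        if len({p.dose for p in self.points}) < 2:
            raise DomainError("a survival dataset needs >= 2 points with distinct doses")

    @property
    def label(self) -> str:
        return (
            f"{self.cell_line}/{self.publication}/{self.beam_type}"
            f"/LET={self.let_kev_um:g}"
        )

    @property
    def doses(self) -> np.ndarray:
        return np.array([p.dose for p in self.points], dtype=float)

    @property
    def sf(self) -> np.ndarray:
        return np.array([p.sf_observed for p in self.points], dtype=float)

    def fit_points(self) -> tuple[np.ndarray, np.ndarray]:
        """(doses, observed SF) with zero-dose points excluded."""
        d, s = self.doses, self.sf
        mask = d > 0
        return d[mask], s[mask]

    @property
    def n_fit_points(self) -> int:
        return int(np.count_nonzero(self.doses > 0))


@dataclass(frozen=True)
class PoissonSurvivalParams:
    """(alpha, beta, m): damage induction rate per Gy, per-damage repair
    probability, and the repairability threshold (default 5)."""

    alpha: float
    beta: float
    m: int = 5

    def __post_init__(self) -> None:
        if not (math.isfinite(self.alpha) and self.alpha > 0):
            raise DomainError(f"alpha must be finite and > 0, got {self.alpha}")
        if not (math.isfinite(self.beta) and 0.0 <= self.beta <= 1.0):
            raise DomainError(f"beta must lie in [0, 1], got {self.beta}")
        if int(self.m) != self.m or self.m < 0:
            raise DomainError(f"m must be a non-negative integer, got {self.m}")


@dataclass(frozen=True)
class LQParams:
    """Linear-quadratic comparator parameters (alpha_lq in /Gy, beta_lq in /Gy^2)."""

    alpha_lq: float
    beta_lq: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.alpha_lq) and self.alpha_lq >= 0):
            raise DomainError(f"alpha_lq must be >= 0, got {self.alpha_lq}")
        if not (math.isfinite(self.beta_lq) and self.beta_lq >= 0):
            raise DomainError(f"beta_lq must be >= 0, got {self.beta_lq}")


def _sf_poisson_raw(dose: np.ndarray, alpha: float, beta: float, m: int) -> np.ndarray:
    """Series evaluation without parameter validation (hot path for fitting)."""
    x = alpha * dose
    bx = beta * x
    total = np.ones_like(x)
    term = np.ones_like(x)
    for n in range(1, int(m) + 1):
        term = term * bx / n
        total = total + term
    return total * np.exp(-x)


def eval_sf_poisson(dose, params: PoissonSurvivalParams):
    """Surviving fraction under the Poisson-threshold model.

    Accepts a scalar dose or an array of doses (Gy).  SF(0) is exactly 1.
    The m+1 series terms are accumulated iteratively
    (term_{n+1} = term_n * beta*alpha*D / (n+1)) and scaled by exp(-alpha*D);
    double precision is exact at the dose scales of clonogenic assays.
    """
    d = np.asarray(dose, dtype=float)
    if np.any(~np.isfinite(d)) or np.any(d < 0):
        raise DomainError("dose must be finite and >= 0")
    out = _sf_poisson_raw(d, params.alpha, params.beta, params.m)
    return out if isinstance(dose, np.ndarray) else float(out)


def eval_sf_lq(dose, params: LQParams):
    """Surviving fraction under the LQ model: exp(-alpha_lq*D - beta_lq*D^2)."""
    d = np.asarray(dose, dtype=float)
    if np.any(~np.isfinite(d)) or np.any(d < 0):
        raise DomainError("dose must be finite and >= 0")
    out = np.exp(-params.alpha_lq * d - params.beta_lq * d * d)
    return out if isinstance(dose, np.ndarray) else float(out)


def _rmspe_raw(predicted: np.ndarray, observed: np.ndarray) -> float:
    r = (predicted - observed) / observed
    return float(np.sqrt(np.mean(r * r)))


def rmspe(predicted, observed) -> float:
    """Root-mean-square percentage error sqrt(mean(((P-O)/O)^2)).

    Both inputs are collections of surviving fractions of equal length;
    observed values must be strictly positive.  Zero-dose points are
    excluded upstream (``SurvivalDataset.fit_points``) — the statistic
    itself is agnostic of dose.
    """
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape:
        raise DomainError(f"length mismatch: {p.shape} vs {o.shape}")
    if p.size == 0:
        raise DomainError("rmspe of empty input is undefined")
    if np.any(o <= 0) or np.any(~np.isfinite(o)) or np.any(~np.isfinite(p)):
        raise DomainError("observed survival fractions must be finite and > 0")
    return _rmspe_raw(p, o)
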