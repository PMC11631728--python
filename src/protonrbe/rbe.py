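"""Proton RBE from isoeffective dose matching.

For a cell line characterised by its photon radiosensitivity (alpha_x,
beta_x), a proton LET, and a photon reference dose D per fraction, the RBE
is obtained in four steps:

1. evaluate the photon surviving fraction SF(D) with (alpha_x, beta_x);
2. map (alpha_x, beta_x, LET) to proton parameters through the linear
   LET-response relations (beta_p clamped into [0, 1]);
3. solve SF_p(D_p) = SF(D) for the proton dose D_p by bracketing and
   root finding (the survival curve is strictly decreasing in dose);
4. RBE = D / D_p.

The "comprehensive" coefficient set pools all cell lines:
a_alpha = 1.12, b_alpha = 0.0019, a_beta = 0.99 and a cell-type-dependent
slope b_beta = 0.013 * alpha_x, i.e.

    alpha_p = (1.12 + 0.0019*LET) * alpha_x
    beta_p  = (0.99 - 0.013*alpha_x*LET) * beta_x

At high LET the extrapolated beta_p crosses zero; it is clamped at 0 (no
repair) and flagged.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import pandas as pd
from scipy import optimize

from .fitting import LETResponseParams, PhotonReference
from .survival import DomainError, PoissonSurvivalParams, eval_sf_poisson

logger = logging.getLogger(__name__)

__all__ = [
    "RBEQuery",
    "RBEResult",
    "comprehensive_let_response",
    "alpha_beta_at_let",
    "solve_dose_for_sf",
    "compute_rbe",
    "rbe_curves",
]

#: Pooled cross-cell-line coefficients of the comprehensive model.
COMPREHENSIVE_A_ALPHA = 1.12
COMPREHENSIVE_B_ALPHA = 0.0019
COMPREHENSIVE_A_BETA = 0.99
COMPREHENSIVE_BBETA_SLOPE = 0.013  # b_beta = 0.013 * alpha_x


def comprehensive_let_response(
    alpha_x: float, bbeta_slope: float = COMPREHENSIVE_BBETA_SLOPE
) -> LETResponseParams:
    """LET-response coefficients of the comprehensive model for a cell line
    with photon radiosensitivity ``alpha_x`` (b_beta scales with alpha_x)."""
    return LETResponseParams(
        a_alpha=COMPREHENSIVE_A_ALPHA,
        b_alpha=COMPREHENSIVE_B_ALPHA,
        a_beta=COMPREHENSIVE_A_BETA,
        b_beta=bbeta_slope * alpha_x,
    )


@dataclass(frozen=True)
class RBEQuery:
    """One RBE evaluation point: photon reference dose per fraction (Gy),
    LET (keV/µm), the cell line's photon parameters, and the LET-response
    coefficients to apply."""

    photon_dose: float
    let_kev_um: float
    photon_ref: PhotonReference
    let_response: LETResponseParams
    m: int = 5

    def __post_init__(self) -> None:
        if not (math.isfinite(self.photon_dose) and self.photon_dose > 0):
            raise DomainError(f"photon dose must be > 0, got {self.photon_dose}")
        if not (math.isfinite(self.let_kev_um) and self.let_kev_um >= 0):
            raise DomainError(f"LET must be >= 0, got {self.let_kev_um}")


@dataclass(frozen=True)
class RBEResult:
    rbe: float
    proton_dose: float
    sf_level: float
    alpha_p: float
    beta_p: float
    beta_clamped: bool


def alpha_beta_at_let(
    photon_ref: PhotonReference,
    let_response: LETResponseParams,
    let: float,
    m: int = 5,
) -> tuple[PoissonSurvivalParams, bool]:
    """Proton (alpha_p, beta_p) at a given LET from the linear relations.

    beta_p is clamped into [0, 1]; the returned flag is True when the raw
    value fell outside (negative beta at extrapolated high LET means the
    damage is treated as unrepairable).
    """
    if not (math.isfinite(let) and let >= 0):
        raise DomainError(f"LET must be >= 0, got {let}")
    alpha_p = (let_response.a_alpha + let_response.b_alpha * let) * photon_ref.alpha_x
    if alpha_p <= 0:
        raise DomainError(f"derived alpha_p = {alpha_p} <= 0 at LET {let}")
    raw_beta = (let_response.a_beta - let_response.b_beta * let) * photon_ref.beta_x
    beta_p = min(max(raw_beta, 0.0), 1.0)
    clamped = beta_p != raw_beta
    if clamped:
        logger.info(
            "LET %.3g: raw beta_p %.4f clamped to %.1f", let, raw_beta, beta_p
        )
    return PoissonSurvivalParams(alpha=alpha_p, beta=beta_p, m=m), clamped


def solve_dose_for_sf(
    target_sf: float,
    params: PoissonSurvivalParams,
    sf_tol: float = 1e-9,
    dose_tol: float = 1e-8,
    max_dose: float = 1e4,
) -> float:
    """Invert the survival curve: dose D with SF(D) = target_sf.

    The curve is strictly decreasing, so a bracket [0, D_max] is grown
    geometrically from 10 Gy and the root refined with Brent's method to
    |dSF| <= ``sf_tol``.
    """
    if not (0.0 < target_sf <= 1.0):
        raise DomainError(f"target SF must lie in (0, 1], got {target_sf}")
    if target_sf == 1.0:
        return 0.0

    def f(d: float) -> float:
        return eval_sf_poisson(d, params) - target_sf

    hi = 10.0
    while f(hi) > 0:
        hi *= 2.0
        if hi > max_dose:
            raise RuntimeError(
                f"no dose below {max_dose} Gy reaches SF {target_sf} "
                f"(alpha={params.alpha}, beta={params.beta}, m={params.m})"
            )
    # refine well below dose_tol: on steep curves the SF tolerance is the
    # binding one and needs extra dose precision
    xtol = min(dose_tol, 1e-13)
    dose = float(optimize.brentq(f, 0.0, hi, xtol=xtol, rtol=8.9e-16))
    if abs(f(dose)) > sf_tol:
        raise RuntimeError(f"root refinement stalled: |dSF| = {abs(f(dose)):.3g}")
    return dose


def compute_rbe(query: RBEQuery) -> RBEResult:
    """RBE = D / D_p at matched surviving fraction (see module docstring).

    The reference dose is the PHOTON dose per fraction; the matched SF is
    evaluated with the photon parameters and the proton dose producing the
    same SF is found by root finding.
    """
    photon_params = PoissonSurvivalParams(
        alpha=query.photon_ref.alpha_x, beta=query.photon_ref.beta_x, m=query.m
    )
    sf_x = eval_sf_poisson(query.photon_dose, photon_params)
    proton_params, clamped = alpha_beta_at_let(
        query.photon_ref, query.let_response, query.let_kev_um, m=query.m
    )
    d_p = solve_dose_for_sf(sf_x, proton_params)
    return RBEResult(
        rbe=query.photon_dose / d_p,
        proton_dose=d_p,
        sf_level=float(sf_x),
        alpha_p=proton_params.alpha,
        beta_p=proton_params.beta,
        beta_clamped=clamped,
    )


def rbe_curves(
    lets,
    doses,
    alpha_xs,
    beta_xs,
    let_response: LETResponseParams | None = None,
    bbeta_slope: float = COMPREHENSIVE_BBETA_SLOPE,
    m: int = 5,
) -> pd.DataFrame:
    """Vectorised RBE over the grid LET × dose × alpha_x × beta_x.

    When ``let_response`` is None the comprehensive model is used, with
    b_beta = ``bbeta_slope`` * alpha_x per cell.  Returns a tidy table with
    one row per grid cell (empty grid → empty table).
    """
    rows = []
    for let, dose, ax, bx in itertools.product(lets, doses, alpha_xs, beta_xs):
        lr = let_response if let_response is not None else comprehensive_let_response(
            ax, bbeta_slope
        )
        ref = PhotonReference(cell_line=f"alpha_x={ax:g}", alpha_x=ax, beta_x=bx)
        res = compute_rbe(RBEQuery(photon_dose=dose, let_kev_um=let,
                                   photon_ref=ref, let_response=lr, m=m))
        rows.append({
            "let_kev_um": let, "dose_gy": dose, "alpha_x": ax, "beta_x": bx,
            "rbe": res.rbe, "proton_dose_gy": res.proton_dose,
            "sf_level": res.sf_level, "alpha_p": res.alpha_p,
            "beta_p": res.beta_p, "beta_clamped": res.beta_clamped,
        })
    columns = ["let_kev_um", "dose_gy", "alpha_x", "beta_x", "rbe",
               "proton_dose_gy", "sf_level", "alpha_p", "beta_p", "beta_clamped"]
    return pd.DataFrame(rows, columns=columns)
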