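"""Curve fitting: single-curve best fits, multi-curve fitting (MCF) under
linear LET-response relations, and the deterioration-index outlier statistic.

MCF fits an entire family of survival curves (one cell line, several LETs)
simultaneously.  Instead of an independent (alpha, beta) per curve, every
curve's parameters are tied to the photon reference (alpha_x, beta_x) of the
cell line through linear ratios in LET:

    alpha_p(LET) = (a_alpha + b_alpha * LET) * alpha_x
    beta_p(LET)  = (a_beta  - b_beta  * LET) * beta_x     (clamped to [0, 1])

and the four coefficients (a_alpha, b_alpha, a_beta, b_beta) are chosen to
minimise the unweighted sum of per-dataset RMSPE.  The cost of forcing exact
linearity is that individual curves may fit worse than their unconstrained
best fit; the deterioration index

    Det = RMSPE_MCF / (RMSPE_best + 0.05)

quantifies that penalty per curve (the 0.05 floor prevents inflated ratios
when the best fit is already excellent).  Det > 4 flags probable
experimental outliers — in practice, curves whose nominal LET is wrong.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .survival import (
    DomainError,
    LQParams,
    PoissonSurvivalParams,
    SurvivalDataset,
    _rmspe_raw,
    _sf_poisson_raw,
    eval_sf_lq,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PhotonReference",
    "LETResponseParams",
    "FitResult",
    "DatasetDiagnostics",
    "MCFResult",
    "SingleVariableMCFResult",
    "CrossCellSummary",
    "fit_single",
    "fit_photon_reference",
    "mcf",
    "det_index",
    "classify_outliers",
    "mcf_single_variable",
    "summarize_across_cell_lines",
    "regress_bbeta_on_alphax",
]

#: Default multi-start grids (deterministic order; tie-break by start index).
_MCF_INTERCEPT_STARTS = (0.8, 1.0, 1.2)
_MCF_SLOPE_STARTS = (0.0, 0.01, 0.03)
_SINGLE_ALPHA_STARTS = (0.3, 1.0, 3.0)
_SINGLE_BETA_STARTS = (0.2, 0.5, 0.8)

_ALPHA_MAX = 20.0  # /Gy, generous bound for clonogenic data
_LQ_MAX = 20.0


@dataclass(frozen=True)
class PhotonReference:
    """Photon-derived (alpha_x, beta_x) for one cell line — the anchor
    against which proton radiosensitivity ratios are expressed."""

    cell_line: str
    alpha_x: float
    beta_x: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.alpha_x) and self.alpha_x > 0):
            raise DomainError(f"alpha_x must be > 0, got {self.alpha_x}")
        if not (math.isfinite(self.beta_x) and 0 < self.beta_x <= 1):
            raise DomainError(f"beta_x must lie in (0, 1], got {self.beta_x}")


@dataclass(frozen=True)
class LETResponseParams:
    """Coefficients of the linear LET relations R_alpha = a_alpha + b_alpha*LET
    and R_beta = a_beta - b_beta*LET (ratios proton/photon)."""

    a_alpha: float
    b_alpha: float
    a_beta: float
    b_beta: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.a_alpha) and self.a_alpha > 0):
            raise DomainError(f"a_alpha must be > 0, got {self.a_alpha}")
        if not (math.isfinite(self.a_beta) and self.a_beta > 0):
            raise DomainError(f"a_beta must be > 0, got {self.a_beta}")
        if not (math.isfinite(self.b_alpha) and self.b_alpha >= 0):
            raise DomainError(f"b_alpha must be >= 0, got {self.b_alpha}")
        if not (math.isfinite(self.b_beta) and self.b_beta >= 0):
            raise DomainError(f"b_beta must be >= 0, got {self.b_beta}")


@dataclass
class FitResult:
    """Outcome of a single-curve best fit (parameters minimising RMSPE)."""

    params: PoissonSurvivalParams | LQParams
    rmspe: float
    n_points: int
    converged: bool


@dataclass
class DatasetDiagnostics:
    """Per-dataset MCF bookkeeping: constrained vs unconstrained fit quality."""

    dataset_id: str
    let_kev_um: float
    rmspe_mcf: float
    rmspe_best: float | None = None
    det: float | None = None
    flag: str | None = None
    beta_clamped: bool = False


@dataclass
class MCFResult:
    cell_line: str
    let_response: LETResponseParams
    photon_ref: PhotonReference
    per_dataset: list[DatasetDiagnostics]
    objective: float  # sum of per-dataset RMSPE at the optimum
    m: int = 5


@dataclass
class SingleVariableMCFResult:
    """Outcome of refitting b_beta alone with the cell-independent
    coefficients (a_alpha, b_alpha, a_beta) held fixed."""

    cell_line: str
    b_beta_hash: float
    fixed: tuple[float, float, float]
    max_det: float
    per_dataset: list[DatasetDiagnostics] = field(default_factory=list)
    objective: float = float("nan")


@dataclass
class CrossCellSummary:
    """Mean and sample (n-1) SD of the LET-response coefficients across cell
    lines; ``bbeta_slope`` is the through-origin coefficient of b_beta^# on
    alpha_x when supplied (see ``regress_bbeta_on_alphax``)."""

    mean_a_alpha: float
    sd_a_alpha: float
    mean_b_alpha: float
    sd_b_alpha: float
    mean_a_beta: float
    sd_a_beta: float
    n_cell_lines: int
    bbeta_slope: float | None = None


# ---------------------------------------------------------------------------
# Single-curve fitting
# ---------------------------------------------------------------------------

def _minimize_multistart(objective, starts, bounds):
    """Bounded L-BFGS-B from each start; best (objective, start order) wins."""
    best = None
    for i, x0 in enumerate(starts):
        res = optimize.minimize(
            objective,
            x0=np.asarray(x0, dtype=float),
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": 1e-14, "gtol": 1e-12, "maxiter": 500},
        )
        key = (res.fun, i)
        if best is None or key < best[0]:
            best = (key, res)
    return best[1]


def fit_single(dataset: SurvivalDataset, model: str = "poisson", m: int = 5) -> FitResult:
    """Best-fit one survival curve by bounded minimisation of RMSPE.

    ``model`` selects the Poisson-threshold model (parameters alpha in
    (0, 20] /Gy, beta in [0, 1], threshold ``m``) or the LQ comparator
    (alpha_lq, beta_lq in [0, 20]).  A fixed multi-start grid makes the
    result deterministic.
    """
    doses, obs = dataset.fit_points()
    if doses.size < 3:
        raise DomainError(
            f"{dataset.label}: need >= 3 non-zero-dose points for a 2-parameter fit, "
            f"got {doses.size}"
        )
    if model == "poisson":
        def objective(theta):
            pred = _sf_poisson_raw(doses, theta[0], theta[1], m)
            return _rmspe_raw(pred, obs)

        starts = list(itertools.product(_SINGLE_ALPHA_STARTS, _SINGLE_BETA_STARTS))
        res = _minimize_multistart(objective, starts, [(1e-6, _ALPHA_MAX), (0.0, 1.0)])
        params: PoissonSurvivalParams | LQParams = PoissonSurvivalParams(
            alpha=float(res.x[0]), beta=float(res.x[1]), m=m
        )
    elif model == "lq":
        def objective(theta):
            pred = np.exp(-theta[0] * doses - theta[1] * doses * doses)
            return _rmspe_raw(pred, obs)

        starts = list(itertools.product((0.1, 0.5, 1.0), (0.01, 0.05, 0.1)))
        res = _minimize_multistart(objective, starts, [(0.0, _LQ_MAX), (0.0, _LQ_MAX)])
        params = LQParams(alpha_lq=float(res.x[0]), beta_lq=float(res.x[1]))
    else:
        raise ValueError(f"unknown model {model!r}; expected 'poisson' or 'lq'")
    if not res.success and not math.isfinite(res.fun):
        raise RuntimeError(f"{dataset.label}: fit failed from all starts: {res.message}")
    return FitResult(params=params, rmspe=float(res.fun), n_points=int(doses.size),
                     converged=bool(res.success))


def fit_photon_reference(
    photon_datasets: list[SurvivalDataset], m: int = 5
) -> PhotonReference:
    """Pool all photon survival points of a cell line and best-fit the
    Poisson-threshold model, yielding the reference (alpha_x, beta_x)."""
    datasets = list(photon_datasets)
    if not datasets:
        raise DomainError(
            "no photon datasets supplied; when a publication reports only LQ "
            "photon parameters, generate a pseudo-photon curve with "
            "synthetic.generate_photon_from_lq first"
        )
    cell_lines = {d.cell_line for d in datasets}
    if len(cell_lines) > 1:
        raise DomainError(f"photon datasets span multiple cell lines: {sorted(cell_lines)}")
    doses = np.concatenate([d.fit_points()[0] for d in datasets])
    obs = np.concatenate([d.fit_points()[1] for d in datasets])
    if doses.size < 3:
        raise DomainError("need >= 3 pooled non-zero-dose photon points")

    def objective(theta):
        pred = _sf_poisson_raw(doses, theta[0], theta[1], m)
        return _rmspe_raw(pred, obs)

    starts = list(itertools.product(_SINGLE_ALPHA_STARTS, _SINGLE_BETA_STARTS))
    res = _minimize_multistart(objective, starts, [(1e-6, _ALPHA_MAX), (0.0, 1.0)])
    # beta_x = 0 would make R_beta ratios meaningless; nudge onto the open interval
    beta_x = max(float(res.x[1]), 1e-9)
    return PhotonReference(cell_line=next(iter(cell_lines)),
                           alpha_x=float(res.x[0]), beta_x=beta_x)


# ---------------------------------------------------------------------------
# Multi-curve fitting
# ---------------------------------------------------------------------------

def _proton_family(datasets: list[SurvivalDataset]):
    """Validate and cache the proton curves of one MCF family."""
    fam = [d for d in datasets if d.radiation == "proton"]
    if len({d.let_kev_um for d in fam}) < 2:
        raise DomainError(
            "MCF needs >= 2 proton datasets with distinct LETs "
            "(slopes are unidentifiable from a single LET)"
        )
    cache = []
    for d in fam:
        doses, obs = d.fit_points()
        if doses.size == 0:
            raise DomainError(f"{d.label}: no non-zero-dose points")
        cache.append((d, d.let_kev_um, doses, obs))
    return cache


def _mcf_objective_factory(cache, photon_ref: PhotonReference, m: int):
    ax, bx = photon_ref.alpha_x, photon_ref.beta_x

    def objective(theta):
        a_a, b_a, a_b, b_b = theta
        total = 0.0
        for _, let, doses, obs in cache:
            alpha_p = (a_a + b_a * let) * ax
            if alpha_p <= 0 or not math.isfinite(alpha_p):
                return 1e6
            beta_p = min(max((a_b - b_b * let) * bx, 0.0), 1.0)
            total += _rmspe_raw(_sf_poisson_raw(doses, alpha_p, beta_p, m), obs)
        return total

    return objective


def mcf(
    datasets: list[SurvivalDataset],
    photon_ref: PhotonReference,
    m: int = 5,
    diagnostics: bool = True,
) -> MCFResult:
    """Multi-curve fit of one cell line's proton survival curves.

    Minimises the unweighted sum of per-dataset RMSPE over the four linear
    LET-response coefficients, with (alpha_x, beta_x) held fixed at the
    photon reference.  Inside the forward model beta_p is clamped to [0, 1]
    so the optimiser can explore steep b_beta without generating invalid
    survival curves; clamping events are logged and recorded per dataset.

    With ``diagnostics=True`` (default) each dataset is additionally
    best-fitted on its own and annotated with RMSPE_best and Det.
    """
    cache = _proton_family(datasets)
    objective = _mcf_objective_factory(cache, photon_ref, m)

    starts = [
        (aa, ab, sa, sb)
        for aa in _MCF_INTERCEPT_STARTS
        for ab in _MCF_INTERCEPT_STARTS
        for sa in _MCF_SLOPE_STARTS
        for sb in _MCF_SLOPE_STARTS
    ]
    # screen the full grid cheaply, then polish the most promising starts
    start_vec = [(aa, sa, ab, sb) for (aa, ab, sa, sb) in starts]
    scored = sorted(
        range(len(start_vec)), key=lambda i: (objective(start_vec[i]), i)
    )
    polish = [start_vec[i] for i in scored[:5]]
    bounds = [(1e-3, 5.0), (0.0, 1.0), (1e-3, 5.0), (0.0, 1.0)]
    res = _minimize_multistart(objective, polish, bounds)
    theta = res.x
    let_response = LETResponseParams(
        a_alpha=float(theta[0]), b_alpha=float(theta[1]),
        a_beta=float(theta[2]), b_beta=float(theta[3]),
    )

    per_dataset: list[DatasetDiagnostics] = []
    ax, bx = photon_ref.alpha_x, photon_ref.beta_x
    total = 0.0
    for d, let, doses, obs in cache:
        alpha_p = (let_response.a_alpha + let_response.b_alpha * let) * ax
        raw_beta = (let_response.a_beta - let_response.b_beta * let) * bx
        beta_p = min(max(raw_beta, 0.0), 1.0)
        clamped = beta_p != raw_beta
        if clamped:
            logger.info("%s: beta_p clamped from %.4f to %.4f", d.label, raw_beta, beta_p)
        r = _rmspe_raw(_sf_poisson_raw(doses, alpha_p, beta_p, m), obs)
        total += r
        diag = DatasetDiagnostics(
            dataset_id=d.label, let_kev_um=let, rmspe_mcf=r, beta_clamped=clamped
        )
        if diagnostics:
            best = fit_single(d, model="poisson", m=m)
            diag.rmspe_best = best.rmspe
            diag.det = det_index(r, best.rmspe)
        per_dataset.append(diag)

    result = MCFResult(
        cell_line=photon_ref.cell_line,
        let_response=let_response,
        photon_ref=photon_ref,
        per_dataset=per_dataset,
        objective=float(total),
        m=m,
    )
    if diagnostics:
        result = classify_outliers(result)
    return result


def det_index(rmspe_mcf: float, rmspe_best: float) -> float:
    """Deterioration index Det = RMSPE_MCF / (RMSPE_best + 0.05)."""
    if rmspe_mcf < 0 or rmspe_best < 0:
        raise DomainError("RMSPE values must be >= 0")
    return rmspe_mcf / (rmspe_best + 0.05)


def classify_outliers(
    result: MCFResult,
    ok_threshold: float = 1.25,
    warn_threshold: float = 2.0,
    outlier_threshold: float = 4.0,
) -> MCFResult:
    """Annotate each dataset's Det with a severity flag.

    Det <= 1.25: deterioration visually undetectable ("ok");
    <= 2: small and acceptable; <= 4: suspicious; > 4: probable outlier
    from experimental error (typically a mis-estimated LET).
    """
    for diag in result.per_dataset:
        if diag.det is None:
            raise DomainError(
                f"{diag.dataset_id}: Det not populated; run mcf with diagnostics=True"
            )
        if diag.det <= ok_threshold:
            diag.flag = "ok"
        elif diag.det <= warn_threshold:
            diag.flag = "acceptable"
        elif diag.det <= outlier_threshold:
            diag.flag = "suspicious"
        else:
            diag.flag = "outlier"
    return result


def mcf_single_variable(
    datasets: list[SurvivalDataset],
    photon_ref: PhotonReference,
    fixed_a_alpha: float,
    fixed_b_alpha: float,
    fixed_a_beta: float,
    m: int = 5,
    diagnostics: bool = True,
) -> SingleVariableMCFResult:
    """Refit b_beta alone, holding (a_alpha, b_alpha, a_beta) at the
    cell-independent averages.  Yields the cell-dependent slope b_beta^#."""
    cache = _proton_family(datasets)
    objective4 = _mcf_objective_factory(cache, photon_ref, m)

    def objective(b_b: float) -> float:
        return objective4((fixed_a_alpha, fixed_b_alpha, fixed_a_beta, b_b))

    res = optimize.minimize_scalar(
        objective, bounds=(0.0, 1.0), method="bounded",
        options={"xatol": 1e-10},
    )
    b_beta_hash = float(res.x)

    per_dataset: list[DatasetDiagnostics] = []
    ax, bx = photon_ref.alpha_x, photon_ref.beta_x
    total = 0.0
    max_det = 0.0
    for d, let, doses, obs in cache:
        alpha_p = (fixed_a_alpha + fixed_b_alpha * let) * ax
        raw_beta = (fixed_a_beta - b_beta_hash * let) * bx
        beta_p = min(max(raw_beta, 0.0), 1.0)
        r = _rmspe_raw(_sf_poisson_raw(doses, alpha_p, beta_p, m), obs)
        total += r
        diag = DatasetDiagnostics(
            dataset_id=d.label, let_kev_um=let, rmspe_mcf=r,
            beta_clamped=beta_p != raw_beta,
        )
        if diagnostics:
            best = fit_single(d, model="poisson", m=m)
            diag.rmspe_best = best.rmspe
            diag.det = det_index(r, best.rmspe)
            max_det = max(max_det, diag.det)
        per_dataset.append(diag)

    return SingleVariableMCFResult(
        cell_line=photon_ref.cell_line,
        b_beta_hash=b_beta_hash,
        fixed=(fixed_a_alpha, fixed_b_alpha, fixed_a_beta),
        max_det=max_det,
        per_dataset=per_dataset,
        objective=float(total),
    )


# ---------------------------------------------------------------------------
# Cross-cell-line summaries
# ---------------------------------------------------------------------------

def summarize_across_cell_lines(results: list[LETResponseParams]) -> CrossCellSummary:
    """Arithmetic mean and sample (n-1) SD of (a_alpha, b_alpha, a_beta)
    over cell lines — the cell-independent coefficients of the
    comprehensive model."""
    if len(results) < 2:
        raise DomainError("need >= 2 cell lines to summarize")
    a_a = np.array([r.a_alpha for r in results])
    b_a = np.array([r.b_alpha for r in results])
    a_b = np.array([r.a_beta for r in results])
    return CrossCellSummary(
        mean_a_alpha=float(a_a.mean()), sd_a_alpha=float(a_a.std(ddof=1)),
        mean_b_alpha=float(b_a.mean()), sd_b_alpha=float(b_a.std(ddof=1)),
        mean_a_beta=float(a_b.mean()), sd_a_beta=float(a_b.std(ddof=1)),
        n_cell_lines=len(results),
    )


def regress_bbeta_on_alphax(pairs: list[tuple[float, float]]) -> float:
    """Through-origin least-squares slope of b_beta^# on alpha_x:
    slope = sum(x*y) / sum(x^2).

    The linear relation has no intercept by construction; intended use is
    >= 2 cell lines, but a single pair (giving the plain ratio y/x) is
    accepted.
    """
    if len(pairs) < 1:
        raise DomainError("need at least one (alpha_x, b_beta) pair")
    x = np.array([p[0] for p in pairs], dtype=float)
    y = np.array([p[1] for p in pairs], dtype=float)
    sxx = float(np.sum(x * x))
    if sxx == 0:
        raise DomainError("all alpha_x are zero; slope undefined")
    return float(np.sum(x * y) / sxx)
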