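"""One-ligand competitive-exchange titration model.

Forward-simulates and inverts CLE-AdCSV (competitive ligand exchange —
adsorptive cathodic stripping voltammetry) titrations under the standard
one-ligand-class model.  At equilibrium, total iron partitions among three
pools:

* Fe'   — inorganic iron (the reference species for conditional constants),
* FeL   — iron bound to the natural ligand L, with conditional constant
          K = [FeL] / ([Fe'][L']), K in L/mol,
* FeSA  — iron bound to the added competing ligand salicylaldoxime (SA),
          summarised by the side-reaction coefficient
          α_SA = [FeSA]/[Fe'] = K1·[SA] (+ β2·[SA]² for the bis complex).

Mass balance Fe_T = [Fe'](1 + α_SA) + K·[Fe']·L_T / (1 + K·[Fe']) reduces to
a quadratic in [Fe'] which is solved in closed form with the numerically
stable root formula.  The measured voltammetric peak current is proportional
to [FeSA]; a titration (Fe additions vs peak current) is inverted either by
the van den Berg / Ruzic linearisation or by weighted nonlinear least
squares on the forward model.

Concentrations are mol/L internally; titration interfaces use nmol/L.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .errors import (
    DegenerateFitError,
    DomainError,
    FitFailureError,
    InsufficientDataError,
)

__all__ = [
    "SpeciationState",
    "TitrationCurve",
    "LigandFit",
    "DEFAULT_SA_CONC",
    "DEFAULT_LOG_K1_FESA",
    "DEFAULT_LOG_BETA2_FESA2",
    "side_reaction_coefficient",
    "default_alpha_sa",
    "solve_one_ligand_equilibrium",
    "simulate_titration",
    "estimate_sensitivity",
    "fit_vdb_linearization",
    "fit_nonlinear",
]

#: Added salicylaldoxime concentration, mol/L.
DEFAULT_SA_CONC = 5e-6

# Conditional Fe'-SA constants for seawater at pH ~8.2, from the CLE-AdCSV
# literature (not measured in this package); overridable everywhere.
DEFAULT_LOG_K1_FESA = 6.45
DEFAULT_LOG_BETA2_FESA2 = 10.72


@dataclass(frozen=True)
class SpeciationState:
    """Equilibrium partition of total iron, all concentrations mol/L."""

    fe_prime: float
    feL: float
    feSA: float
    fe_total: float


@dataclass
class TitrationCurve:
    """One CLE-AdCSV titration: Fe additions (nmol/L) vs peak currents."""

    fe_added: np.ndarray          # nmol/L, non-decreasing
    peak_current: np.ndarray      # arbitrary current units, >= 0
    dfe0: float                   # ambient dissolved Fe, nmol/L
    sa_conc: float = DEFAULT_SA_CONC   # mol/L
    alpha_sa: float | None = None      # dimensionless; default from sa_conc
    ph: float = 8.2
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.fe_added = np.asarray(self.fe_added, dtype=float)
        self.peak_current = np.asarray(self.peak_current, dtype=float)
        if self.fe_added.shape != self.peak_current.shape:
            raise DomainError("fe_added and peak_current must have equal length")
        if self.fe_added.size < 5:
            raise DomainError("a titration needs at least 5 points")
        if np.any(np.diff(self.fe_added) < 0):
            raise DomainError("fe_added must be non-decreasing")
        if np.any(self.peak_current < 0):
            raise DomainError("peak currents must be >= 0")
        if self.alpha_sa is None:
            self.alpha_sa = default_alpha_sa(self.sa_conc)

    @property
    def fe_total(self) -> np.ndarray:
        """Total Fe at each titration point, nmol/L."""
        return self.dfe0 + self.fe_added

    @property
    def n_points(self) -> int:
        return int(self.fe_added.size)


@dataclass(frozen=True)
class LigandFit:
    """Estimated ligand pool from one titration.

    ``L_T`` is the total ligand concentration (nmol/L) and ``logK`` the
    conditional stability constant with respect to Fe'.  Standard errors
    are delta-method (linearisation) or asymptotic (nonlinear).
    """

    L_T: float
    logK: float
    sensitivity: float            # current units per mol/L FeSA
    se_LT: float
    se_logK: float
    method: str                   # "linearization" | "nonlinear"
    n_points: int
    dfe0: float = math.nan        # nmol/L, copied from the curve
    warnings: tuple[str, ...] = ()

    @property
    def excess_ligand(self) -> float:
        """L_T − ambient DFe, nmol/L; negative means saturated ligands."""
        return self.L_T - self.dfe0


def side_reaction_coefficient(
    sa_conc: float,
    K1: float = 10.0 ** DEFAULT_LOG_K1_FESA,
    beta2: float = 10.0 ** DEFAULT_LOG_BETA2_FESA2,
    use_bis: bool = False,
) -> float:
    """α_SA = K1·[SA] + β2·[SA]² (bis term only if ``use_bis``).

    ``sa_conc`` in mol/L, K1 in L/mol, β2 in L²/mol².
    """
    if sa_conc < 0 or K1 < 0 or beta2 < 0:
        raise DomainError("sa_conc and stability constants must be >= 0")
    alpha = K1 * sa_conc
    if use_bis:
        alpha += beta2 * sa_conc * sa_conc
    return alpha


def default_alpha_sa(sa_conc: float = DEFAULT_SA_CONC, use_bis: bool = False) -> float:
    """Side-reaction coefficient with the packaged literature constants."""
    return side_reaction_coefficient(sa_conc, use_bis=use_bis)


def solve_one_ligand_equilibrium(
    fe_total: float, L_T: float, logK: float, alpha_sa: float
) -> SpeciationState:
    """Closed-form equilibrium for the one-ligand model (inputs mol/L).

    [Fe'] is the positive root of  a·f² + b·f + c = 0  with
    a = K(1+α), b = (1+α) + K(L_T − Fe_T), c = −Fe_T, evaluated with the
    cancellation-free quadratic formula (q = −(b + sign(b)·√disc)/2).
    """
    for name, v in (("fe_total", fe_total), ("L_T", L_T),
                    ("logK", logK), ("alpha_sa", alpha_sa)):
        if not math.isfinite(v):
            raise DomainError(f"{name} must be finite, got {v}")
    if fe_total < 0 or L_T < 0 or alpha_sa < 0:
        raise DomainError("concentrations and alpha_sa must be >= 0")
    if fe_total == 0.0:
        return SpeciationState(0.0, 0.0, 0.0, 0.0)

    K = 10.0 ** logK
    one_plus_alpha = 1.0 + alpha_sa
    a = K * one_plus_alpha
    b = one_plus_alpha + K * (L_T - fe_total)
    c = -fe_total
    if a == 0.0:  # K == 0 underflow: no organic complexation
        f = fe_total / one_plus_alpha
    else:
        disc = b * b - 4.0 * a * c          # c <= 0 so disc >= b^2
        q = -0.5 * (b + math.copysign(math.sqrt(disc), b))
        roots = [r for r in (q / a, c / q if q != 0.0 else math.inf) if r > 0]
        f = min(roots)
    feL = fe_total - f * one_plus_alpha
    feL = max(feL, 0.0)  # guard round-off at L_T == 0
    return SpeciationState(f, feL, alpha_sa * f, fe_total)


def simulate_titration(
    dfe0: float,
    L_T: float,
    logK: float,
    additions: Sequence[float] | None = None,
    alpha_sa: float | None = None,
    sa_conc: float = DEFAULT_SA_CONC,
    sensitivity: float = 1e9,
    noise_sd: float = 0.0,
    seed: int | None = None,
    meta: dict | None = None,
) -> TitrationCurve:
    """Forward-simulate a titration; ``dfe0``/``L_T``/additions in nmol/L.

    peak[i] = sensitivity × [FeSA](Fe_T[i]) × (1 + ε_i) with multiplicative
    Gaussian noise ε ~ N(0, noise_sd²).  Any stochastic call requires an
    explicit seed.  Default additions: 10 evenly spaced points over 0–9
    nmol/L.  Negative noisy currents are clipped at zero.
    """
    if noise_sd < 0:
        raise DomainError("noise_sd must be >= 0")
    if noise_sd > 0 and seed is None:
        raise DomainError("a seed is required when noise_sd > 0")
    if additions is None:
        additions = np.linspace(0.0, 9.0, 10)
    additions = np.asarray(additions, dtype=float)
    if np.any(np.diff(additions) < 0):
        raise DomainError("additions must be non-decreasing")
    if alpha_sa is None:
        alpha_sa = default_alpha_sa(sa_conc)

    fesa = np.array([
        solve_one_ligand_equilibrium((dfe0 + add) * 1e-9, L_T * 1e-9, logK, alpha_sa).feSA
        for add in additions
    ])
    peaks = sensitivity * fesa
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        peaks = peaks * (1.0 + rng.normal(0.0, noise_sd, size=peaks.shape))
        peaks = np.clip(peaks, 0.0, None)
    return TitrationCurve(
        fe_added=additions, peak_current=peaks, dfe0=dfe0,
        sa_conc=sa_conc, alpha_sa=alpha_sa, meta=meta or {},
    )


def estimate_sensitivity(curve: TitrationCurve, k_tail: int = 3) -> tuple[float, float]:
    """Internal-calibration sensitivity from the saturated titration tail.

    OLS slope of peak current on total Fe (mol/L) over the last ``k_tail``
    points, corrected by (1+α)/α: once the ligand is saturated every added
    increment partitions between Fe' and FeSA in fixed proportion, so the
    tail slope equals S·α/(1+α).  Returns (sensitivity, SE).
    """
    if not (2 <= k_tail <= curve.n_points):
        raise DomainError(f"k_tail must be in [2, {curve.n_points}], got {k_tail}")
    x = curve.fe_total[-k_tail:] * 1e-9
    y = curve.peak_current[-k_tail:]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateFitError("titration tail carries no slope information")
    alpha = curve.alpha_sa
    corr = (1.0 + alpha) / alpha
    if k_tail == 2:
        slope = (y[1] - y[0]) / (x[1] - x[0])
        return slope * corr, math.nan
    res = stats.linregress(x, y)
    return res.slope * corr, res.stderr * corr


def _back_calculate(curve: TitrationCurve, sensitivity: float):
    """Per-point speciation implied by the measured peaks at sensitivity S."""
    fet = curve.fe_total * 1e-9
    fesa = curve.peak_current / sensitivity
    fe_prime = fesa / curve.alpha_sa
    fel = fet - fe_prime * (1.0 + curve.alpha_sa)
    return fet, fe_prime, fel


def fit_vdb_linearization(
    curve: TitrationCurve, sensitivity: float | None = None
) -> LigandFit:
    """van den Berg / Ruzic linearised fit of the one-ligand model.

    Regresses y = [Fe']/[FeL] on x = [Fe']: under the model
    y = x/L_T + 1/(K·L_T), so L_T = 1/slope and K = slope/intercept.
    Points with non-positive back-calculated [FeL] are dropped with a
    warning.  Standard errors follow from the regression covariance by the
    delta method.
    """
    warns: list[str] = []
    if sensitivity is None:
        sensitivity, _ = estimate_sensitivity(curve)
    if not (sensitivity > 0):
        raise DomainError(f"sensitivity must be > 0, got {sensitivity}")

    _, fe_prime, fel = _back_calculate(curve, sensitivity)
    keep = (fel > 0) & (fe_prime > 0)
    n_drop = int(np.sum(~keep))
    if n_drop:
        msg = f"dropped {n_drop} point(s) with non-positive back-calculated FeL"
        warns.append(msg)
        warnings.warn(msg, stacklevel=2)
    if int(keep.sum()) < 3:
        raise InsufficientDataError(
            f"only {int(keep.sum())} usable point(s) after dropping FeL <= 0"
        )

    x = fe_prime[keep]
    y = fe_prime[keep] / fel[keep]
    res = stats.linregress(x, y)
    slope, intercept = res.slope, res.intercept
    if slope <= 0 or intercept <= 0:
        raise FitFailureError(
            "linearised fit produced non-positive slope or intercept",
            diagnostics={"slope": slope, "intercept": intercept,
                         "n_points": int(keep.sum())},
        )

    L_T = 1.0 / slope * 1e9  # mol/L -> nmol/L
    logK = math.log10(slope / intercept)
    # delta method; Cov(intercept, slope) = -x̄ Var(slope) under OLS
    var_s = res.stderr ** 2
    var_i = res.intercept_stderr ** 2
    cov_si = -float(np.mean(x)) * var_s
    se_LT = math.sqrt(var_s) / slope**2 * 1e9
    ln10 = math.log(10.0)
    var_logK = (var_s / slope**2 + var_i / intercept**2
                - 2.0 * cov_si / (slope * intercept)) / ln10**2
    se_logK = math.sqrt(max(var_logK, 0.0))

    fit = LigandFit(
        L_T=L_T, logK=logK, sensitivity=sensitivity,
        se_LT=se_LT, se_logK=se_logK, method="linearization",
        n_points=int(keep.sum()), dfe0=curve.dfe0, warnings=tuple(warns),
    )
    if fit.excess_ligand < 0:
        warnings.warn("fitted L_T below ambient DFe (saturated ligands)",
                      stacklevel=2)
        fit = replace(fit, warnings=fit.warnings + ("negative excess ligand",))
    return fit


def _model_peaks(curve: TitrationCurve, L_T_nM: float, logK: float, sens: float):
    return np.array([
        sens * solve_one_ligand_equilibrium(
            ft * 1e-9, L_T_nM * 1e-9, logK, curve.alpha_sa).feSA
        for ft in curve.fe_total
    ])


def _heuristic_init(curve: TitrationCurve, sensitivity: float | None = None) -> LigandFit:
    """Fallback starting values when the linearisation fails.

    L_T from the x-intercept of the saturated tail line (the classic
    graphical ligand estimate) and logK from a coarse grid search at that
    L_T and sensitivity.
    """
    if sensitivity is None:
        sensitivity, _ = estimate_sensitivity(curve)
    x = curve.fe_total[-3:]
    y = curve.peak_current[-3:]
    res = stats.linregress(x, y)
    lt0 = -res.intercept / res.slope if res.slope > 0 else curve.dfe0
    lt0 = min(max(lt0, 0.05), float(curve.fe_total[-1]))
    grid = np.arange(9.0, 13.6, 0.25)
    costs = [float(np.sum((_model_peaks(curve, lt0, k, sensitivity)
                           - curve.peak_current) ** 2)) for k in grid]
    return LigandFit(
        L_T=lt0, logK=float(grid[int(np.argmin(costs))]),
        sensitivity=sensitivity, se_LT=math.nan, se_logK=math.nan,
        method="heuristic-init", n_points=curve.n_points, dfe0=curve.dfe0,
    )


def fit_nonlinear(
    curve: TitrationCurve,
    init: LigandFit | None = None,
    sensitivity: float | None = None,
    max_nfev: int = 2000,
) -> LigandFit:
    """Complete (nonlinear least-squares) fit of the one-ligand model.

    Minimises the squared residuals of observed vs modelled peak currents
    over (L_T, logK, sensitivity), initialised from the linearised fit
    unless ``init`` is supplied.  When the linearisation itself fails (its
    near-zero intercept often fits negative on noisy strong-ligand curves)
    a heuristic start is used instead: the tail-line x-intercept for L_T
    and a coarse logK grid search.  Asymptotic standard errors come from
    the Jacobian at the optimum.  The optimiser starts at the
    initialisation so the residual sum never increases relative to it.
    """
    if init is None:
        try:
            init = fit_vdb_linearization(curve, sensitivity=sensitivity)
        except (FitFailureError, InsufficientDataError):
            init = _heuristic_init(curve, sensitivity=sensitivity)
    y = curve.peak_current
    scale = float(np.max(y))
    if scale <= 0:
        raise FitFailureError("all peak currents are zero")

    def residuals(theta: np.ndarray) -> np.ndarray:
        lt, logk, log_s = theta
        return (_model_peaks(curve, lt, logk, 10.0 ** log_s) - y) / scale

    x0 = np.array([max(init.L_T, 1e-6),
                   min(max(init.logK, 6.0), 16.0),
                   math.log10(init.sensitivity)])
    sol = optimize.least_squares(
        residuals, x0,
        bounds=([0.0, 6.0, -np.inf], [np.inf, 16.0, np.inf]),
        x_scale=[max(init.L_T, 1.0), 1.0, 1.0],
        max_nfev=max_nfev,
    )
    if not sol.success:
        raise FitFailureError(
            f"nonlinear fit did not converge: {sol.message}",
            diagnostics={"nfev": sol.nfev, "cost": sol.cost},
            best={"L_T": sol.x[0], "logK": sol.x[1],
                  "sensitivity": 10.0 ** sol.x[2]},
        )

    lt, logk, log_s = sol.x
    dof = max(curve.n_points - 3, 1)
    s2 = 2.0 * sol.cost / dof
    try:
        cov = np.linalg.inv(sol.jac.T @ sol.jac) * s2
        se_lt, se_logk = math.sqrt(cov[0, 0]), math.sqrt(cov[1, 1])
    except np.linalg.LinAlgError:
        se_lt = se_logk = math.nan

    warns: tuple[str, ...] = ()
    if lt < curve.dfe0:
        warns = ("negative excess ligand",)
    return LigandFit(
        L_T=float(lt), logK=float(logk), sensitivity=float(10.0 ** log_s),
        se_LT=float(se_lt), se_logK=float(se_logk), method="nonlinear",
        n_points=curve.n_points, dfe0=curve.dfe0, warnings=warns,
    )
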