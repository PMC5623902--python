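"""Combination index, nonlinear blending, and the categorical synergy call.

The combination index (CI) at the 50% normalized-viability level is

    CI = dA / D_A50 + dB / D_B50

for a combination ``(dA, dB)`` achieving 50% viability, with ``D_A50``,
``D_B50`` the single-agent iso-effect doses.  CI < 0.7 is called synergy,
CI > 1.3 subadditivity, and 0.7-1.3 additivity.  When either single agent
fails to reach 50% inhibition within the tested range the CI is not
available and the nonlinear-blending statistic takes over: the excess (in
percentage points of inhibition) of the best mixture along a
fixed-total-scaled-dose ray over the better of its two single-agent
endpoints, with >20 called synergy and <-20 subadditivity (antagonism).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .dose_response import inverse_hill
from .response_surface import (
    Checkerboard,
    SurfaceParams,
    extract_isobole,
    fit_surface,
    isobole_dose_b,
    level_reciprocals,
    predict_surface,
)

logger = logging.getLogger("combosurf")

__all__ = [
    "SynergyReport",
    "BlendingRaySpec",
    "CIResult",
    "compute_ci",
    "compute_blending",
    "classify",
    "analyze_combination",
    "LABELS",
]

LABELS = ("synergy", "additivity", "subadditivity")
#: "antagonism" is the Methods-text synonym for worse-than-additive calls.
LABEL_ALIASES = {"antagonism": "subadditivity"}

DEFAULT_THRESHOLDS = {
    "ci_synergy": 0.7,
    "ci_subadditive": 1.3,
    "blending_synergy": 20.0,
    "blending_subadditive": -20.0,
}


@dataclass(frozen=True)
class BlendingRaySpec:
    """Ray construction for the nonlinear-blending statistic.

    Each drug's dose is scaled by ``scaling`` (by default the maximum
    tested concentration), and the ray holds the total scaled dose fixed
    at ``total_scaled_dose`` while the mixture fraction x sweeps 0..1:
    the dose pair is ``(x * t * scale_a, (1 - x) * t * scale_b)``.
    """

    scaling: tuple[float, float]
    total_scaled_dose: float = 1.0
    n_fractions: int = 101

    def __post_init__(self) -> None:
        sa, sb = self.scaling
        if not (sa > 0 and sb > 0):
            raise ValueError("scaling concentrations must be > 0")
        if not (0 < self.total_scaled_dose <= 1.0):
            raise ValueError("total_scaled_dose must lie in (0, 1]")
        if self.n_fractions < 21:
            raise ValueError("n_fractions must be >= 21")


@dataclass(frozen=True)
class CIResult:
    """Combination index summary at the 50% viability level.

    ``ci`` is the headline value, evaluated where the equipotent ray
    (dA/D_A50 = dB/D_B50) crosses the 50% isobole — a fixed-ratio
    statistic that is exactly 1 under Loewe additivity, below 1 for
    synergy and above 1 for antagonism.  ``ci_min_isobole`` is the
    minimum of dA/D_A50 + dB/D_B50 over the whole fitted contour (the
    most favorable tested combination); because the contour's axis
    intercepts always score exactly 1 this minimum is capped at 1 and
    serves as a synergy-side diagnostic, not a two-sided measure.
    """

    ci: float
    point: tuple[float, float]  # (dose_a, dose_b) where the headline CI holds, nM
    ci_min_isobole: float
    min_point: tuple[float, float]
    at: str = "equipotent"  # or "min-isobole" when the ray crossing left the grid


@dataclass
class SynergyReport:
    """End-to-end synergy call for one cell-line/drug-pair experiment."""

    ci: float  # NaN = not available
    ci_point: tuple[float, float] | None
    ci_min_isobole: float
    blending: float
    label: str
    basis: str  # "ci" or "blending"
    diagnostics: dict = field(default_factory=dict)
    cell_line: str = ""

    @property
    def ci_available(self) -> bool:
        return math.isfinite(self.ci)


def _is_na(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


def compute_ci(
    params: SurfaceParams,
    dose_ranges: tuple[float, float],
    n_points: int = 201,
) -> CIResult | None:
    """Minimum combination index over the fitted 50%-viability isobole.

    Returns None (not available) when either marginal fails to reach 50%
    viability within the tested dose range — the condition that routes
    classification to the blending fallback — or when the fitted surface
    never crosses 50% inside the tested rectangle.

    The headline CI is evaluated at the equipotent-ray crossing of the
    contour; the contour-minimum CI (grid sweep plus bounded 1-D polish)
    is reported alongside.  See :class:`CIResult` for why the minimum
    cannot flag antagonism and the ray crossing can.
    """
    max_a, max_b = float(dose_ranges[0]), float(dose_ranges[1])
    d_a50 = inverse_hill(params.marginal_a, 0.5)
    d_b50 = inverse_hill(params.marginal_b, 0.5)
    if _is_na(d_a50) or d_a50 > max_a or _is_na(d_b50) or d_b50 > max_b:
        logger.info("CI not available: a marginal does not reach 50%% in range")
        return None

    contour = extract_isobole(params, 0.5, (max_a, max_b), n_points=n_points)
    if not contour.available:
        return None

    da = contour.points[:, 0]
    db = contour.points[:, 1]
    ci_vals = da / d_a50 + db / d_b50
    k = int(np.argmin(ci_vals))
    best_ci = float(ci_vals[k])
    best_pt = (float(da[k]), float(db[k]))

    # polish along the contour (dose_a parameterizes it; dose_b is closed form)
    def contour_ci(x: float) -> float:
        y = isobole_dose_b(params, 0.5, x)
        if not np.isfinite(y) or y > max_b:
            return np.inf
        return x / d_a50 + y / d_b50

    lo = da[max(k - 1, 0)]
    hi = da[min(k + 1, da.size - 1)]
    if hi > lo:
        res = minimize_scalar(contour_ci, bounds=(float(lo), float(hi)),
                              method="bounded",
                              options={"xatol": 1e-12 * max(d_a50, 1.0)})
        if np.isfinite(res.fun) and res.fun < best_ci:
            best_ci = float(res.fun)
            x = float(res.x)
            best_pt = (x, float(isobole_dose_b(params, 0.5, x)))

    equip = _equipotent_ci(params, d_a50, d_b50, max_a, max_b)
    if math.isfinite(equip):
        u = equip / 2.0
        return CIResult(
            ci=equip,
            point=(u * d_a50, u * d_b50),
            ci_min_isobole=best_ci,
            min_point=best_pt,
            at="equipotent",
        )
    # strong antagonism pushed the ray crossing outside the tested grid;
    # fall back to the contour minimum so a CI is still reported
    return CIResult(
        ci=best_ci,
        point=best_pt,
        ci_min_isobole=best_ci,
        min_point=best_pt,
        at="min-isobole",
    )


def _equipotent_ci(params, d_a50, d_b50, max_a, max_b) -> float:
    """CI where the equipotent ray (dA/D_A50 = dB/D_B50) crosses 50% viability.

    Along the ray (u * D_A50, u * D_B50) the implicit equation at 50%
    viability is quadratic in u: c2 u^2 + 2u - 1 = 0 with
    c2 = alpha * D_A50 * D_B50 * q(0.5); CI = 2u at the crossing.
    """
    _, _, inv_pa, inv_pb = level_reciprocals(params, 0.5)
    q = math.sqrt(inv_pa * inv_pb / (params.ec50_a * params.ec50_b))
    c2 = params.alpha * d_a50 * d_b50 * q
    if abs(c2) < 1e-14:
        u = 0.5
    else:
        u = (-1.0 + math.sqrt(1.0 + c2)) / c2
    if u * d_a50 > max_a or u * d_b50 > max_b:
        return math.nan  # crossing lies outside the tested rectangle
    return 2.0 * u


def compute_blending(params: SurfaceParams, ray: BlendingRaySpec) -> float:
    """Nonlinear-blending value along the fixed-total-scaled-dose ray.

    inhibition(x) = 100 * (1 - viability) at the mixture
    ``(x * t * scale_a, (1 - x) * t * scale_b)``; the statistic is the
    maximum over interior mixture fractions of inhibition(x) minus the
    better endpoint inhibition, in percentage points.  A grid sweep of
    ``n_fractions`` points is polished with a bounded 1-D maximizer.
    """
    sa, sb = ray.scaling
    t = ray.total_scaled_dose

    def inhibition(x):
        x = np.asarray(x, dtype=float)
        v = predict_surface(params, x * t * sa, (1.0 - x) * t * sb)
        return 100.0 * (1.0 - np.asarray(v))

    xs = np.linspace(0.0, 1.0, ray.n_fractions)
    inh = inhibition(xs)
    end = max(float(inh[0]), float(inh[-1]))
    k = int(np.argmax(inh[1:-1])) + 1
    best = float(inh[k])

    lo, hi = xs[max(k - 1, 0)], xs[min(k + 1, xs.size - 1)]
    res = minimize_scalar(
        lambda x: -float(inhibition(x)), bounds=(float(lo), float(hi)),
        method="bounded", options={"xatol": 1e-10},
    )
    best = max(best, -float(res.fun))
    return best - end


def classify(
    ci: float | None,
    blending: float | None,
    thresholds: dict | None = None,
) -> tuple[str, str]:
    """Categorical synergy call with CI precedence.

    When a CI is available it decides the label (CI < 0.7 synergy,
    CI > 1.3 subadditivity, the closed interval 0.7-1.3 additivity) even
    if the blending value alone would say otherwise.  Only when the CI is
    not available does the blending value decide (> 20 synergy, < -20
    subadditivity, the closed interval [-20, 20] additivity).

    Returns ``(label, basis)`` with basis "ci" or "blending".
    """
    th = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        th.update(thresholds)
    ci_na = _is_na(ci)
    bl_na = _is_na(blending)
    if ci_na and bl_na:
        raise ValueError("both CI and blending are not available; cannot classify")
    if not ci_na:
        if ci < th["ci_synergy"]:
            return "synergy", "ci"
        if ci > th["ci_subadditive"]:
            return "subadditivity", "ci"
        return "additivity", "ci"
    if blending > th["blending_synergy"]:
        return "synergy", "blending"
    if blending < th["blending_subadditive"]:
        return "subadditivity", "blending"
    return "additivity", "blending"


def analyze_combination(board: Checkerboard, config=None) -> SynergyReport:
    """Full pipeline on a normalized checkerboard.

    Fits the marginals and the nine-parameter surface, computes the CI at
    50% viability (falling back to not-available when a single agent
    cannot reach 50% inhibition in range), evaluates nonlinear blending on
    the max-concentration-scaled ray, and classifies.  Every intermediate
    lands in ``report.diagnostics``.

    ``board.viability`` must already be normalized (vehicle mean = 1);
    use :func:`combosurf.interface.read_checkerboard_csv` /
    :func:`combosurf.dose_response.normalize_viability` for raw signals.
    """
    from .interface import RunConfig  # late import: interface builds on this module

    cfg = config or RunConfig()
    try:
        surface, diag = fit_surface(
            board,
            n_restarts=cfg.surface_restarts,
            seed=cfg.seed,
            hill_restarts=cfg.hill_restarts,
        )
    except ValueError as err:
        raise ValueError(f"surface fitting stage: {err}") from err

    max_a = float(board.doses_a.max())
    max_b = float(board.doses_b.max())

    ci_res = compute_ci(surface, (max_a, max_b), n_points=cfg.isobole_points)
    ray = BlendingRaySpec(
        scaling=(max_a, max_b),
        total_scaled_dose=cfg.blending_total,
        n_fractions=cfg.blending_fractions,
    )
    blending = compute_blending(surface, ray)

    ci = ci_res.ci if ci_res is not None else math.nan
    label, basis = classify(
        None if ci_res is None else ci, blending, cfg.thresholds
    )
    report = SynergyReport(
        ci=ci,
        ci_point=None if ci_res is None else ci_res.point,
        ci_min_isobole=math.nan if ci_res is None else ci_res.ci_min_isobole,
        blending=blending,
        label=label,
        basis=basis,
        diagnostics={
            "surface_params": surface.to_dict(),
            "surface_fit": diag.to_dict(),
            "ci_at": None if ci_res is None else ci_res.at,
            "marginal_a": surface.marginal_a.to_dict(),
            "marginal_b": surface.marginal_b.to_dict(),
            "dose_ranges_nM": [max_a, max_b],
            "ci_available": ci_res is not None,
            "unreliable": not diag.converged,
        },
    )
    if not diag.converged:
        logger.warning("surface fit flagged non-converged; metrics marked unreliable")
    return report
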