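"""Single-agent four-parameter Hill (log-logistic) dose-response curves.

Viability is normalized so the vehicle mean is 1.0; "inhibition" means
``100 * (1 - viability)`` percentage points throughout the package.  The
model is the standard inhibitory Hill curve

    E(d) = e_zero + (e_inf - e_zero) * (d/ec50)^h / (1 + (d/ec50)^h)

with ``e_inf <= e_zero`` so predicted viability is monotone non-increasing
in dose.  Doses are nanomolar unless stated otherwise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

logger = logging.getLogger("combosurf")

__all__ = [
    "HillParams",
    "DoseSeries",
    "FitDiagnostics",
    "normalize_viability",
    "predict_hill",
    "fit_hill",
    "inverse_hill",
]

# Exponents beyond this would overflow exp(); the logistic saturates anyway.
_EXP_CLIP = 700.0


@dataclass(frozen=True)
class HillParams:
    """Four-parameter Hill curve for one agent.

    Parameters
    ----------
    e_zero : float
        Normalized viability at zero dose (dimensionless, ~1 after
        vehicle normalization).
    e_inf : float
        Viability asymptote at infinite dose; ``e_inf <= e_zero``
        (inhibitory assay convention).
    ec50 : float
        Midpoint concentration in nM, strictly positive.
    hill : float
        Slope coefficient, strictly positive.
    """

    e_zero: float
    e_inf: float
    ec50: float
    hill: float

    def __post_init__(self) -> None:
        if not (self.ec50 > 0):
            raise ValueError(f"ec50 must be > 0, got {self.ec50}")
        if not (self.hill > 0):
            raise ValueError(f"hill must be > 0, got {self.hill}")
        if self.e_inf > self.e_zero + 1e-12:
            raise ValueError(
                f"e_inf ({self.e_inf}) must not exceed e_zero ({self.e_zero})"
            )

    def to_dict(self) -> dict:
        return {
            "e_zero": self.e_zero,
            "e_inf": self.e_inf,
            "ec50_nM": self.ec50,
            "hill": self.hill,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HillParams":
        return cls(d["e_zero"], d["e_inf"], d["ec50_nM"], d["hill"])


@dataclass(frozen=True)
class DoseSeries:
    """Replicate-resolved single-agent dose-response series.

    ``doses`` is strictly increasing with a leading 0 (vehicle);
    ``viabilities`` has one row per dose and one column per replicate
    (NaN marks a missing replicate well).
    """

    doses: np.ndarray
    viabilities: np.ndarray
    drug: str = "drug"

    def __post_init__(self) -> None:
        doses = np.asarray(self.doses, dtype=float)
        viab = np.atleast_2d(np.asarray(self.viabilities, dtype=float))
        object.__setattr__(self, "doses", doses)
        object.__setattr__(self, "viabilities", viab)
        if doses.ndim != 1 or doses.size < 2:
            raise ValueError("doses must be a 1-D vector with >= 2 entries")
        if doses[0] != 0:
            raise ValueError("first dose must be 0 (vehicle)")
        if np.any(np.diff(doses) <= 0):
            raise ValueError("doses must be strictly increasing")
        if viab.shape[0] != doses.size:
            raise ValueError(
                f"viability rows ({viab.shape[0]}) must match doses ({doses.size})"
            )
        finite = viab[np.isfinite(viab)]
        if finite.size and finite.min() < 0:
            raise ValueError("negative viabilities; apply the clipping policy first")
        if np.any(np.all(~np.isfinite(viab), axis=1)):
            raise ValueError("every dose needs at least one replicate reading")

    @property
    def n_nonzero_doses(self) -> int:
        return int(np.sum(self.doses > 0))

    def flat_points(self) -> tuple[np.ndarray, np.ndarray]:
        """All (dose, viability) replicate points, NaN wells dropped."""
        d = np.repeat(self.doses, self.viabilities.shape[1])
        v = self.viabilities.ravel()
        keep = np.isfinite(v)
        return d[keep], v[keep]


@dataclass
class FitDiagnostics:
    """Bookkeeping for a nonlinear fit."""

    residual_sum_squares: float
    converged: bool
    n_restarts_used: int
    bound_hits: list[str] = field(default_factory=list)
    degenerate: bool = False
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "residual_sum_squares": self.residual_sum_squares,
            "converged": self.converged,
            "n_restarts_used": self.n_restarts_used,
            "bound_hits": list(self.bound_hits),
            "degenerate": self.degenerate,
            "seed": self.seed,
        }


def normalize_viability(
    raw_signal_matrix,
    vehicle_wells,
    doses=None,
    drug: str = "drug",
) -> DoseSeries:
    """Normalize raw well signals to the mean vehicle signal.

    Parameters
    ----------
    raw_signal_matrix : array-like, shape (n_doses, n_replicates)
        Raw luminescence readings at each nonzero dose.
    vehicle_wells : array-like
        Raw readings of the zero-dose (vehicle) wells.
    doses : array-like, optional
        The nonzero doses (nM) matching the rows of ``raw_signal_matrix``.
        Defaults to 1..n_doses placeholders when only normalization is
        wanted.

    Returns
    -------
    DoseSeries
        Dose 0 plus the supplied doses; viability = signal / mean(vehicle),
        so the vehicle row averages 1.0.  Negative normalized values are
        clipped to 0 with a logged warning.
    """
    raw = np.atleast_2d(np.asarray(raw_signal_matrix, dtype=float))
    vehicle = np.asarray(vehicle_wells, dtype=float).ravel()
    if vehicle.size == 0 or not np.any(np.isfinite(vehicle)):
        raise ValueError("missing vehicle (zero-dose) wells")
    vmean = float(np.nanmean(vehicle))
    if not (vmean > 0):
        raise ValueError(f"vehicle mean signal must be > 0, got {vmean}")

    if doses is None:
        doses = np.arange(1, raw.shape[0] + 1, dtype=float)
    doses = np.asarray(doses, dtype=float)
    if doses.size != raw.shape[0]:
        raise ValueError("doses must match raw_signal_matrix rows")

    norm = raw / vmean
    n_neg = int(np.sum(norm < 0))
    if n_neg:
        logger.warning("clipped %d negative normalized viabilities to 0", n_neg)
        norm = np.clip(norm, 0.0, None)

    n_rep = max(norm.shape[1], vehicle.size)
    rows = np.full((doses.size + 1, n_rep), np.nan)
    rows[0, : vehicle.size] = np.clip(vehicle / vmean, 0.0, None)
    rows[1:, : norm.shape[1]] = norm
    return DoseSeries(np.concatenate([[0.0], doses]), rows, drug=drug)


def _hill_fraction(dose, ec50: float, hill: float):
    """(d/ec50)^h / (1 + (d/ec50)^h), overflow-safe, 0 at d = 0."""
    d = np.asarray(dose, dtype=float)
    out = np.zeros_like(d)
    pos = d > 0
    z = hill * (np.log(d[pos]) - math.log(ec50))
    out[pos] = 1.0 / (1.0 + np.exp(np.clip(-z, -_EXP_CLIP, _EXP_CLIP)))
    return out


def predict_hill(params: HillParams, dose):
    """Predicted normalized viability at ``dose`` (scalar or array, nM)."""
    d = np.asarray(dose, dtype=float)
    if np.any(d < 0):
        raise ValueError("dose must be >= 0")
    frac = _hill_fraction(d, params.ec50, params.hill)
    out = params.e_zero + (params.e_inf - params.e_zero) * frac
    return float(out) if np.isscalar(dose) or out.ndim == 0 else out


def inverse_hill(params: HillParams, target_viability: float) -> float:
    """Dose (nM) at which the curve crosses ``target_viability``.

    Closed-form inversion of the Hill equation.  Returns NaN (the
    not-available marker) when the target lies outside the open interval
    ``(e_inf, e_zero)`` — an effect level the curve never attains — which
    is what gates combination-index availability downstream.  A target
    exactly at either asymptote is an error (the dose would be 0 or
    infinite).
    """
    t = float(target_viability)
    if t == params.e_zero or t == params.e_inf:
        raise ValueError(
            f"target {t} sits exactly on an asymptote ({params.e_inf}, {params.e_zero})"
        )
    if not (params.e_inf < t < params.e_zero):
        return math.nan
    ratio = (params.e_zero - t) / (t - params.e_inf)
    return params.ec50 * ratio ** (1.0 / params.hill)


def default_hill_bounds(doses: np.ndarray) -> dict[str, tuple[float, float]]:
    """Default fit box: covers published cytotoxicity assays."""
    nz = doses[doses > 0]
    return {
        "e_zero": (0.8, 1.2),
        "e_inf": (0.0, 1.0),
        "ec50": (float(nz.min()) / 10.0, float(nz.max()) * 10.0),
        "hill": (0.2, 10.0),
    }


def _theta_to_params(theta) -> HillParams:
    e0, einf, log_ec50, hill = theta
    einf = min(einf, e0)  # box cannot encode e_inf <= e_zero; clip at readout
    return HillParams(e0, einf, 10.0 ** log_ec50, hill)


def _hill_residuals(theta, d, v):
    e0, einf, log_ec50, hill = theta
    frac = _hill_fraction(d, 10.0 ** log_ec50, hill)
    return e0 + (einf - e0) * frac - v


def fit_hill(
    series: DoseSeries,
    bounds: dict[str, tuple[float, float]] | None = None,
    n_restarts: int = 16,
    seed: int = 0,
) -> tuple[HillParams | None, FitDiagnostics]:
    """Fit a Hill curve to all replicate points by bounded least squares.

    Replicates are fitted jointly (not averaged), doses enter the
    objective exactly (the zero dose uses the model value ``e_zero``, no
    pseudo-dose), and ec50 is optimized on a log10 scale.  The fit is
    multi-started from a heuristic initial guess plus ``n_restarts - 1``
    points of a scrambled Sobol sequence over the bounds; the best
    residual sum of squares wins.

    Returns ``(params, diagnostics)``.  A series whose mean viability
    spans less than 0.05 is flagged degenerate (flat curve): ``params``
    is None and no ec50 is reported.
    """
    if series.n_nonzero_doses < 4:
        raise ValueError("need at least 4 distinct nonzero doses to fit")
    d, v = series.flat_points()
    box = default_hill_bounds(series.doses)
    if bounds:
        box.update(bounds)

    means = np.nanmean(series.viabilities, axis=1)
    if float(means.max() - means.min()) < 0.05:
        logger.warning("flat dose-response (range < 0.05): degenerate fit")
        return None, FitDiagnostics(
            residual_sum_squares=float(np.sum((v - v.mean()) ** 2)),
            converged=False,
            n_restarts_used=0,
            degenerate=True,
            seed=seed,
        )

    lo = np.array(
        [box["e_zero"][0], box["e_inf"][0], math.log10(box["ec50"][0]), box["hill"][0]]
    )
    hi = np.array(
        [box["e_zero"][1], box["e_inf"][1], math.log10(box["ec50"][1]), box["hill"][1]]
    )

    starts = [_heuristic_start(series, lo, hi)]
    if n_restarts > 1:
        sob = qmc.Sobol(d=4, scramble=True, seed=seed)
        n_draw = 2 ** math.ceil(math.log2(n_restarts - 1))
        u = sob.random(n_draw)[: n_restarts - 1]
        starts.extend(lo + u * (hi - lo))

    best = None
    n_used = 0
    for x0 in starts:
        n_used += 1
        res = least_squares(
            _hill_residuals,
            np.clip(x0, lo, hi),
            bounds=(lo, hi),
            args=(d, v),
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
            max_nfev=400,
        )
        rss = float(np.sum(res.fun**2))
        if best is None or rss < best[0] - 1e-15:
            best = (rss, res)
        if rss < 1e-16:  # numerically exact; further restarts cannot improve
            break

    rss, res = best
    params = _theta_to_params(res.x)
    names = ["e_zero", "e_inf", "ec50", "hill"]
    tol = (hi - lo) * 1e-6
    hits = [
        n
        for n, x, l, h, t in zip(names, res.x, lo, hi, tol)
        if x - l < t or h - x < t
    ]
    diag = FitDiagnostics(
        residual_sum_squares=rss,
        converged=bool(res.success),
        n_restarts_used=n_used,
        bound_hits=hits,
        seed=seed,
    )
    return params, diag


def _heuristic_start(series: DoseSeries, lo, hi):
    """Data-driven initial guess: anchors at the curve's extremes."""
    means = np.nanmean(series.viabilities, axis=1)
    e0 = means[0]
    einf = means[-1]
    mid = (e0 + einf) / 2.0
    nz = series.doses[1:]
    idx = int(np.argmin(np.abs(means[1:] - mid)))
    guess = np.array([e0, min(einf, e0), math.log10(nz[idx]), 1.0])
    return np.clip(guess, lo, hi)
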