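"""Nine-parameter two-drug Loewe response surface and isobole extraction.

The surface couples two marginal Hill curves through an implicit
Loewe-interaction equation.  At a dose pair ``(dA, dB)`` the predicted
viability ``E`` solves

    dA / DA(E) + dB / DB(E)
        + alpha * dA * dB / sqrt(PA(E) * PB(E) * ec50_a * ec50_b)  =  1

where ``DA``/``DB`` are the marginal inverse-Hill dose functions (taken as
+infinity for effects deeper than the marginal asymptote, so the term
vanishes) and ``PA``/``PB`` are potency functions — inverse Hill curves
with the shared combination asymptote ``e_inf_ab`` in place of the
marginal one — which keep the interaction term active below both marginal
asymptotes and let a positive-``alpha`` combination reach effects neither
single agent attains.  The geometric-mean denominator is the classical
Greco interaction scaling; it keeps the interaction term of the same
order as the marginal terms at both ends of the effect range, so the
equation stays solvable for moderate antagonism (``alpha >= -1`` on
grids spanning a few ec50 multiples).  When ``e_inf_ab`` coincides with
both marginal asymptotes the equation is exactly the Greco model.

Properties, by construction:

* on either axis the surface reproduces the marginal Hill curve exactly;
* ``alpha = 0`` is Loewe additivity — every iso-effect contour satisfies
  ``dA/DA(E) + dB/DB(E) = 1`` and the combination index is 1;
* ``alpha > 0`` bends isoboles toward the origin (synergy), ``alpha < 0``
  away (antagonism); ``alpha >= -1`` keeps the root bracketed on tested
  grids.

The nine parameters: e_zero; (e_inf_a, ec50_a, hill_a); (e_inf_b, ec50_b,
hill_b); alpha; e_inf_ab.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from .dose_response import (
    DoseSeries,
    FitDiagnostics,
    HillParams,
    fit_hill,
    inverse_hill,
    predict_hill,
)

logger = logging.getLogger("combosurf")

__all__ = [
    "SurfaceParams",
    "Checkerboard",
    "IsoboleContour",
    "predict_surface",
    "fit_surface",
    "extract_isobole",
    "isobole_dose_b",
    "level_reciprocals",
]

_BISECT_ITERS = 48  # unit-span bracket -> interval ~3.6e-15, below tolerances
_EXP_CLIP = 700.0


@dataclass(frozen=True)
class SurfaceParams:
    """The nine scalar parameters of the combination response surface."""

    e_zero: float
    e_inf_a: float
    ec50_a: float
    hill_a: float
    e_inf_b: float
    ec50_b: float
    hill_b: float
    alpha: float
    e_inf_ab: float

    def __post_init__(self) -> None:
        for name in ("ec50_a", "ec50_b"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be > 0")
        for name in ("hill_a", "hill_b"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be > 0")
        if not math.isfinite(self.alpha):
            raise ValueError(f"alpha must be finite, got {self.alpha}")
        # Strongly negative alpha leaves the implicit equation without a
        # root on deep dose grids; that is checked where doses are known
        # (prediction and fitting), not here.
        emin = min(self.e_inf_a, self.e_inf_b)
        if self.e_inf_ab > emin + 1e-9:
            raise ValueError(
                f"e_inf_ab ({self.e_inf_ab}) must not exceed the lower marginal "
                f"asymptote ({emin})"
            )
        if not (self.e_inf_ab < self.e_zero):
            raise ValueError("e_inf_ab must lie strictly below e_zero")

    @property
    def marginal_a(self) -> HillParams:
        return HillParams(self.e_zero, self.e_inf_a, self.ec50_a, self.hill_a)

    @property
    def marginal_b(self) -> HillParams:
        return HillParams(self.e_zero, self.e_inf_b, self.ec50_b, self.hill_b)

    def to_dict(self) -> dict:
        return {
            "e_zero": self.e_zero,
            "e_inf_a": self.e_inf_a,
            "ec50_a_nM": self.ec50_a,
            "hill_a": self.hill_a,
            "e_inf_b": self.e_inf_b,
            "ec50_b_nM": self.ec50_b,
            "hill_b": self.hill_b,
            "alpha": self.alpha,
            "e_inf_ab": self.e_inf_ab,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SurfaceParams":
        return cls(
            d["e_zero"],
            d["e_inf_a"],
            d.get("ec50_a_nM", d.get("ec50_a")),
            d["hill_a"],
            d["e_inf_b"],
            d.get("ec50_b_nM", d.get("ec50_b")),
            d["hill_b"],
            d["alpha"],
            d["e_inf_ab"],
        )


@dataclass(frozen=True)
class Checkerboard:
    """Two-drug dose grid with replicate viability readings.

    ``viability[i, j, r]`` is replicate ``r`` at ``(doses_a[i],
    doses_b[j])``; NaN marks a missing well.  Both dose vectors start at 0,
    so the single-agent rows/columns and the double-vehicle well are part
    of the grid.
    """

    doses_a: np.ndarray
    doses_b: np.ndarray
    viability: np.ndarray
    drug_a: str = "drug_a"
    drug_b: str = "drug_b"

    def __post_init__(self) -> None:
        da = np.asarray(self.doses_a, dtype=float)
        db = np.asarray(self.doses_b, dtype=float)
        v = np.asarray(self.viability, dtype=float)
        if v.ndim == 2:
            v = v[:, :, None]
        object.__setattr__(self, "doses_a", da)
        object.__setattr__(self, "doses_b", db)
        object.__setattr__(self, "viability", v)
        for name, d in (("doses_a", da), ("doses_b", db)):
            if d.ndim != 1 or d.size < 2 or d[0] != 0 or np.any(np.diff(d) <= 0):
                raise ValueError(
                    f"{name} must start at 0 (vehicle) and be strictly increasing"
                )
        if v.shape[:2] != (da.size, db.size):
            raise ValueError(
                f"viability shape {v.shape[:2]} does not match grid "
                f"({da.size}, {db.size})"
            )
        if not np.any(np.isfinite(v[0, 0])):
            raise ValueError("the double-vehicle (0, 0) well is missing")
        finite = v[np.isfinite(v)]
        if finite.size and finite.min() < 0:
            raise ValueError("negative viabilities; normalize/clip first")

    @property
    def n_replicates(self) -> int:
        return self.viability.shape[2]

    def axis_series(self, axis: str) -> DoseSeries:
        """Single-agent series along one axis (the other drug at 0)."""
        if axis == "a":
            return DoseSeries(self.doses_a, self.viability[:, 0, :], drug=self.drug_a)
        if axis == "b":
            return DoseSeries(self.doses_b, self.viability[0, :, :], drug=self.drug_b)
        raise ValueError("axis must be 'a' or 'b'")

    def flat_wells(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """All finite wells as flat (dose_a, dose_b, viability) vectors."""
        da = np.repeat(self.doses_a, self.doses_b.size)
        db = np.tile(self.doses_b, self.doses_a.size)
        da = np.repeat(da, self.n_replicates)
        db = np.repeat(db, self.n_replicates)
        v = self.viability.ravel()
        keep = np.isfinite(v)
        return da[keep], db[keep], v[keep]


@dataclass(frozen=True)
class IsoboleContour:
    """Iso-effect contour of the surface at one viability level."""

    effect_level: float
    points: np.ndarray  # (n, 2) ordered (dose_a, dose_b) pairs, nM
    axis_intercepts: tuple[float, float]  # single-agent iso-doses, NaN = NA

    @property
    def available(self) -> bool:
        return self.points.shape[0] > 0


def _inv_dose_reciprocal(E, e_zero, e_inf, ec50, hill):
    """1 / D(E) for the Hill curve, vectorized; 0 where E <= e_inf.

    D(E) is the dose at which the curve crosses viability E.  Values of E
    at or below the asymptote are unreachable (D = +inf), encoded as a
    zero reciprocal so the corresponding Loewe term vanishes.
    """
    E = np.asarray(E, dtype=float)
    out = np.zeros_like(E)
    ok = E > e_inf  # callers keep E < e_zero
    num = E[ok] - e_inf
    den = e_zero - E[ok]
    logr = (np.log(num) - np.log(den)) / hill
    out[ok] = np.exp(np.clip(logr, -_EXP_CLIP, _EXP_CLIP)) / ec50
    return out


def _loewe_gap(E, da, db, p: SurfaceParams):
    """LHS - 1 of the implicit interaction equation; increasing in E for alpha >= 0.

    Fused log-space evaluation (this sits inside the fitting loop's
    bisection): reciprocal iso-effect doses come out as exp((log(E - e_inf)
    - log(e_zero - E))/h)/ec50, with log(0) = -inf giving an exact zero
    term for unreachable marginals.
    """
    with np.errstate(divide="ignore"):
        lden = np.log(p.e_zero - E)
        la = np.log(np.maximum(E - p.e_inf_a, 0.0))
        lb = np.log(np.maximum(E - p.e_inf_b, 0.0))
        ra = np.exp(np.minimum((la - lden) / p.hill_a, _EXP_CLIP)) / p.ec50_a
        rb = np.exp(np.minimum((lb - lden) / p.hill_b, _EXP_CLIP)) / p.ec50_b
        g = da * ra + db * rb - 1.0
        if p.alpha != 0.0:
            lab = np.log(np.maximum(E - p.e_inf_ab, 0.0))
            expo = (lab - lden) * (0.5 / p.hill_a + 0.5 / p.hill_b)
            q = np.exp(np.minimum(expo, _EXP_CLIP)) / (p.ec50_a * p.ec50_b)
            g = g + p.alpha * da * db * q
    return g


def _bisect(p, da, db, lo, hi):
    for _ in range(_BISECT_ITERS):
        mid = 0.5 * (lo + hi)
        up = _loewe_gap(mid, da, db, p) > 0
        hi = np.where(up, mid, hi)
        lo = np.where(up, lo, mid)
    return 0.5 * (lo + hi)


def _solve_combination(p: SurfaceParams, da, db):
    """Vectorized root solve for the viability of strictly-positive dose pairs.

    For ``alpha >= 0`` the gap is monotone increasing in E and diverges to
    +inf at the top of the range, so plain bisection applies.  For
    ``alpha < 0`` the negative interaction term wins near the zero-dose
    asymptote and the gap can cross zero twice; the physical root — the
    one continuously connected to the additive (alpha = 0) solution — is
    the lowest crossing, located by a coarse ascending scan before
    bisection.  Dose pairs where the gap never turns positive have no
    solution (the model's known breakdown for strong antagonism at deep
    doses) and raise, naming the offending pair.
    """
    n = da.size
    span = p.e_zero - p.e_inf_ab
    lo = np.full(n, p.e_inf_ab)
    hi = np.full(n, p.e_zero)
    if p.alpha >= 0:
        return _bisect(p, da, db, lo, hi)

    n_scan = 65
    grid = p.e_inf_ab + span * np.linspace(0.0, 1.0, n_scan + 1)[1:-1]
    pos = np.zeros(n, dtype=bool)
    lo_s = lo.copy()
    hi_s = hi.copy()
    prev = np.full(n, p.e_inf_ab)
    for e in grid:
        g = _loewe_gap(np.full(n, e), da, db, p)
        newly = (~pos) & (g > 0)
        lo_s[newly] = prev[newly]
        hi_s[newly] = e
        pos |= newly
        prev = np.where(pos, prev, e)
    # the top probe catches wells whose first positive value sits above the scan
    probe = p.e_zero - 1e-9 * span
    g_top = _loewe_gap(np.full(n, probe), da, db, p)
    newly = (~pos) & (g_top > 0)
    lo_s[newly] = prev[newly]
    hi_s[newly] = probe
    pos |= newly
    if not np.all(pos):
        i = int(np.argmax(~pos))
        raise RuntimeError(
            f"implicit surface equation has no solution at dose pair "
            f"({da[i]:g}, {db[i]:g}) nM (alpha={p.alpha:g} too antagonistic "
            f"for this dose range)"
        )
    return _bisect(p, da, db, lo_s, hi_s)


def predict_surface(params: SurfaceParams, dose_a, dose_b):
    """Predicted viability of the combination at ``(dose_a, dose_b)``.

    Scalar or broadcastable arrays of nonnegative doses (nM).  Axis doses
    reduce exactly to the marginal Hill curves; interior dose pairs solve
    the implicit interaction equation by bisection.
    """
    da = np.asarray(dose_a, dtype=float)
    db = np.asarray(dose_b, dtype=float)
    if np.any(da < 0) or np.any(db < 0):
        raise ValueError("doses must be >= 0")
    da, db = np.broadcast_arrays(da, db)
    scalar = da.ndim == 0
    da = np.atleast_1d(da).ravel().astype(float)
    db = np.atleast_1d(db).ravel().astype(float)

    out = np.empty_like(da)
    both = (da > 0) & (db > 0)
    a_only = (da > 0) & ~both
    b_only = (db > 0) & ~both
    vehicle = ~(both | a_only | b_only)
    out[vehicle] = params.e_zero
    if np.any(a_only):
        out[a_only] = predict_hill(params.marginal_a, da[a_only])
    if np.any(b_only):
        out[b_only] = predict_hill(params.marginal_b, db[b_only])
    if np.any(both):
        out[both] = _solve_combination(params, da[both], db[both])
    if scalar:
        return float(out[0])
    return out.reshape(np.broadcast_shapes(np.shape(dose_a), np.shape(dose_b)))


# --------------------------------------------------------------------------
# Surface fitting
# --------------------------------------------------------------------------

_PARAM_NAMES = (
    "e_zero",
    "e_inf_a",
    "ec50_a",
    "hill_a",
    "e_inf_b",
    "ec50_b",
    "hill_b",
    "alpha",
    "e_inf_ab",
)


def _theta_to_surface(theta) -> SurfaceParams:
    """Optimizer vector -> SurfaceParams.

    ec50s are carried as log10; the ninth coordinate is u in [0, 1] with
    e_inf_ab = u * min(e_inf_a, e_inf_b), which enforces the asymptote
    ordering inside a plain box.
    """
    e0, einf_a, lca, ha, einf_b, lcb, hb, alpha, u = theta
    einf_a = min(einf_a, e0)
    einf_b = min(einf_b, e0)
    emin = min(einf_a, einf_b)
    e_inf_ab = u * emin
    if e_inf_ab >= e0:  # pathological flat corner; nudge below e_zero
        e_inf_ab = e0 - 1e-6
    return SurfaceParams(
        e0, einf_a, 10.0**lca, ha, einf_b, 10.0**lcb, hb, alpha, e_inf_ab
    )


def default_surface_bounds(board: Checkerboard) -> dict[str, tuple[float, float]]:
    nza = board.doses_a[board.doses_a > 0]
    nzb = board.doses_b[board.doses_b > 0]
    return {
        "e_zero": (0.8, 1.2),
        "e_inf_a": (0.0, 1.0),
        "ec50_a": (float(nza.min()) / 10.0, float(nza.max()) * 10.0),
        "hill_a": (0.2, 10.0),
        "e_inf_b": (0.0, 1.0),
        "ec50_b": (float(nzb.min()) / 10.0, float(nzb.max()) * 10.0),
        "hill_b": (0.2, 10.0),
        "alpha": (-5.0, 100.0),
        "u_inf_ab": (0.0, 1.0),
    }


def _surface_residuals(theta, da, db, v):
    p = _theta_to_surface(theta)
    try:
        return predict_surface(p, da, db) - v
    except RuntimeError:
        # trial alpha too antagonistic for this grid: penalize, keep finite
        return np.full_like(v, 10.0)


def fit_surface(
    board: Checkerboard,
    bounds: dict[str, tuple[float, float]] | None = None,
    n_restarts: int = 4,
    seed: int = 0,
    hill_restarts: int = 8,
) -> tuple[SurfaceParams, FitDiagnostics]:
    """Joint bounded least squares of the nine-parameter surface.

    All wells — vehicle, single-agent and combination — enter one
    unweighted objective.  The marginals are initialized from ``fit_hill``
    on the axis data with ``alpha = 0``; further restarts perturb the
    interaction coordinates (and jitter the marginals) from a scrambled
    Sobol sequence.  Returns the best-RSS fit with diagnostics.
    """
    if np.sum(board.doses_a > 0) < 5 or np.sum(board.doses_b > 0) < 5:
        raise ValueError("surface fitting needs a grid of at least 5x5 nonzero doses")
    da, db, v = board.flat_wells()
    box = default_surface_bounds(board)
    if bounds:
        box.update(bounds)

    lo = np.array(
        [
            box["e_zero"][0],
            box["e_inf_a"][0],
            math.log10(box["ec50_a"][0]),
            box["hill_a"][0],
            box["e_inf_b"][0],
            math.log10(box["ec50_b"][0]),
            box["hill_b"][0],
            box["alpha"][0],
            box["u_inf_ab"][0],
        ]
    )
    hi = np.array(
        [
            box["e_zero"][1],
            box["e_inf_a"][1],
            math.log10(box["ec50_a"][1]),
            box["hill_a"][1],
            box["e_inf_b"][1],
            math.log10(box["ec50_b"][1]),
            box["hill_b"][1],
            box["alpha"][1],
            box["u_inf_ab"][1],
        ]
    )

    x0 = _marginal_start(board, lo, hi, seed, hill_restarts)
    starts = [x0]
    if n_restarts > 1:
        sob = qmc.Sobol(d=9, scramble=True, seed=seed + 1)
        n_draw = 2 ** math.ceil(math.log2(n_restarts - 1))
        u = sob.random(n_draw)[: n_restarts - 1]
        for row in u:
            x = x0.copy()
            # jitter marginals within 15% of the box, resample interaction
            width = hi - lo
            x[:7] = np.clip(x0[:7] + (row[:7] - 0.5) * 0.3 * width[:7], lo[:7], hi[:7])
            x[7] = lo[7] + row[7] * (hi[7] - lo[7])
            x[8] = lo[8] + row[8] * (hi[8] - lo[8])
            starts.append(x)

    best = None
    n_used = 0
    any_success = False
    for x in starts:
        n_used += 1
        res = least_squares(
            _surface_residuals,
            np.clip(x, lo, hi),
            bounds=(lo, hi),
            args=(da, db, v),
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-12,
            max_nfev=300,
        )
        rss = float(np.sum(res.fun**2))
        any_success = any_success or bool(res.success)
        if best is None or rss < best[0] - 1e-15:
            best = (rss, res)
        if rss < 1e-16:
            break

    rss, res = best
    params = _theta_to_surface(res.x)
    tol = (hi - lo) * 1e-6
    hits = [
        n
        for n, x, l, h, t in zip(_PARAM_NAMES, res.x, lo, hi, tol)
        if x - l < t or h - x < t
    ]
    if not any_success:
        logger.warning("surface fit did not converge in %d restarts", n_used)
    diag = FitDiagnostics(
        residual_sum_squares=rss,
        converged=any_success,
        n_restarts_used=n_used,
        bound_hits=hits,
        seed=seed,
    )
    return params, diag


def _marginal_start(board, lo, hi, seed, hill_restarts):
    """Initial theta from single-agent fits on the axis data, alpha = 0."""
    guess = np.array(
        [1.0, 0.1, 0.5 * (lo[2] + hi[2]), 1.0, 0.1, 0.5 * (lo[5] + hi[5]), 1.0, 0.0, 0.9]
    )
    for axis, sl in (("a", slice(1, 4)), ("b", slice(4, 7))):
        try:
            p, d = fit_hill(board.axis_series(axis), n_restarts=hill_restarts, seed=seed)
        except ValueError:
            p = None
        if p is not None:
            if axis == "a":
                guess[0] = p.e_zero
            else:
                guess[0] = 0.5 * (guess[0] + p.e_zero)
            guess[sl] = [p.e_inf, math.log10(p.ec50), p.hill]
    return np.clip(guess, lo, hi)


# --------------------------------------------------------------------------
# Isoboles
# --------------------------------------------------------------------------


def level_reciprocals(
    params: SurfaceParams, effect_level: float
) -> tuple[float, float, float, float]:
    """(1/DA, 1/DB, 1/PA, 1/PB) at one effect level.

    DA/DB are the marginal iso-effect doses (reciprocal 0 when the
    marginal cannot reach the level); PA/PB are the potency doses using
    the combined asymptote ``e_inf_ab``.
    """
    p = params
    if not (p.e_inf_ab < effect_level < p.e_zero):
        raise ValueError(
            f"effect level {effect_level} outside the surface's range "
            f"({p.e_inf_ab}, {p.e_zero})"
        )
    E = np.array([effect_level])
    ra = float(_inv_dose_reciprocal(E, p.e_zero, p.e_inf_a, p.ec50_a, p.hill_a)[0])
    rb = float(_inv_dose_reciprocal(E, p.e_zero, p.e_inf_b, p.ec50_b, p.hill_b)[0])
    pa = float(_inv_dose_reciprocal(E, p.e_zero, p.e_inf_ab, p.ec50_a, p.hill_a)[0])
    pb = float(_inv_dose_reciprocal(E, p.e_zero, p.e_inf_ab, p.ec50_b, p.hill_b)[0])
    return ra, rb, pa, pb


def isobole_dose_b(params: SurfaceParams, effect_level: float, dose_a):
    """Closed-form dose_b on the iso-effect contour at ``effect_level``.

    With the effect fixed, the implicit interaction equation is linear in
    dose_b:

        db = (1 - da / DA(E)) / (1 / DB(E) + alpha * da * q(E))

    with ``q(E) = 1 / sqrt(PA(E) PB(E) ec50_a ec50_b)``.  Returns NaN
    where the contour does not cross (the surface already sits below the
    level at ``(dose_a, 0)``, or a negative-alpha denominator
    degenerates).  Vectorized over ``dose_a``.
    """
    p = params
    ra, rb, pa, pb = level_reciprocals(params, effect_level)
    q = math.sqrt(pa * pb / (p.ec50_a * p.ec50_b))
    da = np.asarray(dose_a, dtype=float)
    scalar = da.ndim == 0
    da = np.atleast_1d(da)
    num = 1.0 - da * ra
    den = rb + p.alpha * da * q
    with np.errstate(divide="ignore", invalid="ignore"):
        db = np.where((num >= 0) & (den > 0), num / den, np.nan)
    return float(db[0]) if scalar else db


def extract_isobole(
    params: SurfaceParams,
    effect_level: float = 0.5,
    dose_ranges: tuple[float, float] | None = None,
    n_points: int = 101,
) -> IsoboleContour:
    """Iso-effect contour at ``effect_level`` within the tested rectangle.

    For each of ``n_points`` dose_a values spanning ``[0, max_a]`` the
    matching dose_b is root-solved; dose_a values where the level is not
    bracketed inside ``[0, max_b]`` are omitted (no extrapolation).  The
    axis intercepts come from the closed-form marginal inversion and are
    NaN when the marginal never crosses the level within range.
    """
    if dose_ranges is None:
        raise ValueError("dose_ranges (max_a, max_b) is required — no extrapolation")
    max_a, max_b = float(dose_ranges[0]), float(dose_ranges[1])
    if max_a <= 0 or max_b <= 0:
        raise ValueError("dose ranges must be positive")

    icpt_a = inverse_hill(params.marginal_a, effect_level)
    icpt_b = inverse_hill(params.marginal_b, effect_level)
    if np.isfinite(icpt_a) and icpt_a > max_a:
        icpt_a = math.nan
    if np.isfinite(icpt_b) and icpt_b > max_b:
        icpt_b = math.nan

    # Beyond the marginal-A axis crossing the surface already sits below the
    # level at dose_b = 0, so no downward crossing in dose_b exists there;
    # concentrate the sweep on the reachable span when the intercept is in range.
    da_upper = icpt_a if math.isfinite(icpt_a) else max_a
    da = np.linspace(0.0, da_upper, n_points)
    db = isobole_dose_b(params, effect_level, da)
    keep = np.isfinite(db) & (db <= max_b)  # omit points leaving the rectangle
    points = np.column_stack([da[keep], db[keep]])
    if points.shape[0] == 0:
        logger.info("effect level %.3g unreachable inside the tested range", effect_level)
    return IsoboleContour(
        effect_level=float(effect_level),
        points=points,
        axis_intercepts=(float(icpt_a), float(icpt_b)),
    )
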