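"""Synthetic checkerboards, dose series, and xenograft cohorts with known truth.

Every generator is a pure function of its spec and seed, so each pipeline
stage can be tested against ground truth without external data.  Defaults
emulate a standard two-drug checkerboard: a 9-dose half-log design per
drug plus vehicle, duplicate wells, and multiplicative lognormal noise
with sigma 0.05 (a typical luminescence-assay CV).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dose_response import DoseSeries, HillParams, predict_hill
from .response_surface import Checkerboard, SurfaceParams, predict_surface

logger = logging.getLogger("combosurf")

__all__ = [
    "SyntheticSpec",
    "half_log_grid",
    "surface_preset",
    "preset_grids",
    "generate_checkerboard",
    "generate_bliss_board",
    "generate_resistance_pair",
    "generate_xenograft_cohort",
    "expected_t_over_c",
    "PRESET_NAMES",
]

PRESET_NAMES = ("loewe-null", "synergy", "antagonism")


def half_log_grid(max_dose: float, n: int = 8) -> np.ndarray:
    """Vehicle plus ``n`` half-log-spaced doses ending at ``max_dose`` (nM)."""
    if not (max_dose > 0 and n >= 2):
        raise ValueError("need max_dose > 0 and n >= 2")
    doses = max_dose * 10.0 ** (-0.5 * np.arange(n - 1, -1, -1))
    return np.concatenate([[0.0], doses])


def surface_preset(name: str) -> SurfaceParams:
    """Named ground-truth surfaces for the standard study conditions.

    ``loewe-null`` is exact additivity (alpha = 0); ``synergy`` is a
    strong interaction (alpha = 5) with both agents reaching 80%
    inhibition; ``antagonism`` bends isoboles away from the origin.
    """
    if name == "loewe-null":
        return SurfaceParams(1.0, 0.10, 100.0, 1.2, 0.15, 200.0, 1.5, 0.0, 0.10)
    if name == "synergy":
        return SurfaceParams(1.0, 0.20, 100.0, 1.2, 0.20, 200.0, 1.5, 5.0, 0.05)
    if name == "antagonism":
        return SurfaceParams(1.0, 0.10, 100.0, 1.2, 0.15, 200.0, 1.5, -0.5, 0.10)
    raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")


def preset_grids(name: str) -> tuple[np.ndarray, np.ndarray]:
    """Default dose grids per preset (9-dose half-log designs plus vehicle).

    Synergy/null grids run deep (100x each ec50) so the asymptotes are
    identifiable; the antagonism grid stays within a few ec50 multiples,
    the region where the negative-interaction surface is well posed.
    """
    if name == "antagonism":
        return half_log_grid(316.0, 8), half_log_grid(632.0, 8)
    return half_log_grid(10_000.0, 8), half_log_grid(20_000.0, 8)


@dataclass(frozen=True)
class SyntheticSpec:
    """Ground truth, grid design, noise model and seed for one board."""

    truth: SurfaceParams | str = "loewe-null"
    doses_a: np.ndarray | None = None
    doses_b: np.ndarray | None = None
    replicates: int = 2
    noise_model: str = "multiplicative"  # or "additive"
    sigma: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        default_a, default_b = preset_grids(
            self.truth if isinstance(self.truth, str) else ""
        )
        object.__setattr__(
            self,
            "doses_a",
            default_a if self.doses_a is None else np.asarray(self.doses_a, float),
        )
        object.__setattr__(
            self,
            "doses_b",
            default_b if self.doses_b is None else np.asarray(self.doses_b, float),
        )
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.noise_model not in ("multiplicative", "additive"):
            raise ValueError("noise_model must be 'multiplicative' or 'additive'")

    @property
    def surface(self) -> SurfaceParams:
        if isinstance(self.truth, str):
            return surface_preset(self.truth)
        return self.truth


def _apply_noise(clean: np.ndarray, spec: SyntheticSpec, rng) -> tuple[np.ndarray, int]:
    if spec.sigma == 0:
        return clean.copy(), 0
    if spec.noise_model == "multiplicative":
        noisy = clean * np.exp(rng.normal(0.0, spec.sigma, size=clean.shape))
    else:
        noisy = clean + rng.normal(0.0, spec.sigma, size=clean.shape)
    n_clipped = int(np.sum(noisy < 0))
    if n_clipped:
        frac = n_clipped / noisy.size
        if frac >= 0.01:
            logger.warning("noise model clipped %.1f%% of wells at 0", 100 * frac)
        noisy = np.clip(noisy, 0.0, None)
    return noisy, n_clipped


def generate_checkerboard(spec: SyntheticSpec) -> tuple[Checkerboard, dict]:
    """Simulate a checkerboard from the spec's ground-truth surface.

    Returns the board plus a truth record (parameters, noise settings,
    clip count) for recovery tests.  Identical specs and seeds reproduce
    identical boards.
    """
    truth = spec.surface
    rng = np.random.default_rng(spec.seed)
    da = spec.doses_a[:, None]
    db = spec.doses_b[None, :]
    clean = predict_surface(truth, np.broadcast_to(da, (da.size, db.size)),
                            np.broadcast_to(db, (da.size, db.size)))
    clean = np.repeat(clean[:, :, None], spec.replicates, axis=2)
    noisy, n_clipped = _apply_noise(clean, spec, rng)
    board = Checkerboard(spec.doses_a, spec.doses_b, noisy)
    record = {
        "surface_params": truth.to_dict(),
        "noise_model": spec.noise_model,
        "sigma": spec.sigma,
        "replicates": spec.replicates,
        "seed": spec.seed,
        "n_clipped": n_clipped,
    }
    return board, record


def generate_bliss_board(
    marginal_a: HillParams,
    marginal_b: HillParams,
    doses_a: np.ndarray,
    doses_b: np.ndarray,
    noise_model: str = "multiplicative",
    sigma: float = 0.05,
    replicates: int = 2,
    seed: int = 0,
) -> Checkerboard:
    """Independence-null board: combination viability = product of marginals.

    A robustness fixture — Bliss independence is not the package's
    headline model.  With unit ``e_zero`` marginals, either dose at 0
    reduces to the other marginal.
    """
    doses_a = np.asarray(doses_a, dtype=float)
    doses_b = np.asarray(doses_b, dtype=float)
    va = predict_hill(marginal_a, doses_a)[:, None]
    vb = predict_hill(marginal_b, doses_b)[None, :]
    clean = np.repeat((va * vb)[:, :, None], replicates, axis=2)
    spec = SyntheticSpec(
        truth="loewe-null", doses_a=doses_a, doses_b=doses_b,
        replicates=replicates, noise_model=noise_model, sigma=sigma, seed=seed,
    )
    noisy, _ = _apply_noise(clean, spec, np.random.default_rng(seed))
    return Checkerboard(doses_a, doses_b, noisy)


def generate_resistance_pair(
    parent_ec50: float = 53.0,
    resistant_ec50: float = 20_000.0,
    doses: np.ndarray | None = None,
    noise_model: str = "multiplicative",
    sigma: float = 0.03,
    replicates: int = 3,
    seed: int = 0,
) -> tuple[DoseSeries, DoseSeries]:
    """Parental/resistant single-agent pair differing only in ec50.

    Defaults mirror a cytarabine-resistance scenario: the parental line's
    midpoint at 53 nM (0.053 uM) sits inside a grid capped at 10 uM,
    while the resistant line's midpoint lies beyond it, so the resistant
    series never reaches 50% inhibition in range — the condition that
    forces the combination-index NA path and the blending fallback.
    """
    if not (resistant_ec50 > parent_ec50):
        raise ValueError("resistant_ec50 must exceed parent_ec50")
    if doses is None:
        doses = half_log_grid(10_000.0, 9)
    doses = np.asarray(doses, dtype=float)
    rng = np.random.default_rng(seed)
    out = []
    for name, ec50 in (("parent", parent_ec50), ("resistant", resistant_ec50)):
        p = HillParams(1.0, 0.0, ec50, 1.0)
        clean = np.repeat(predict_hill(p, doses)[:, None], replicates, axis=1)
        spec = SyntheticSpec(
            replicates=replicates, noise_model=noise_model, sigma=sigma, seed=seed
        )
        noisy, _ = _apply_noise(clean, spec, rng)
        out.append(DoseSeries(doses, noisy, drug=name))
    return out[0], out[1]


def expected_t_over_c(
    growth_rate: float, multiplier: float, start_day: int, end_day: int
) -> float:
    """Closed-form T/C% for exponential growth with a rate multiplier."""
    num = math.exp(growth_rate * multiplier * end_day) - math.exp(
        growth_rate * multiplier * start_day
    )
    den = math.exp(growth_rate * end_day) - math.exp(growth_rate * start_day)
    return 100.0 * num / den


def generate_xenograft_cohort(
    growth_rate: float = 0.10,
    effect_multipliers: dict[str, float] | None = None,
    n_per_group: int = 5,
    days: tuple[int, ...] = (0, 3, 7, 10, 14, 17, 21),
    sigma: float = 0.05,
    seed: int = 0,
    baseline_volume: float = 150.0,
    aspect: float = 0.7,
) -> pd.DataFrame:
    """Caliper measurement table for exponential-growth xenograft groups.

    Each group's tumors grow as ``V(t) = V0 * exp(growth_rate * m * t)``
    with group multiplier ``m`` (1 = vehicle-like growth, 0 = stasis) and
    per-animal, per-day lognormal noise; volumes are rendered as
    length/width pairs with a fixed width:length aspect ratio so that
    ``length * width^2 * 0.5`` recovers the volume.  The matching
    closed-form T/C% is :func:`expected_t_over_c`.
    """
    if effect_multipliers is None:
        effect_multipliers = {"vehicle": 1.0, "treated": 0.3}
    if n_per_group < 3:
        raise ValueError("n_per_group must be >= 3")
    rng = np.random.default_rng(seed)
    rows = []
    aid = 0
    for group, m in effect_multipliers.items():
        for _ in range(n_per_group):
            aid += 1
            v0 = baseline_volume * math.exp(rng.normal(0.0, sigma))
            for day in days:
                v = v0 * math.exp(growth_rate * m * day)
                v *= math.exp(rng.normal(0.0, sigma))
                length = (2.0 * v / aspect**2) ** (1.0 / 3.0)
                rows.append(
                    {
                        "animal_id": f"A{aid:03d}",
                        "group": group,
                        "day": int(day),
                        "length_mm": length,
                        "width_mm": aspect * length,
                    }
                )
    return pd.DataFrame(rows)
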