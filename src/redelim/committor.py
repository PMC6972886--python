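"""Committor analysis: transition-state candidate selection and shooting.

Candidate transition-state frames are picked from a CV time series by
rectangular windows around the string's saddle point (±0.05 Å in
methyl–methyl distance, ±0.005 in coordination number by default).  The
commitment probability of a candidate point is then estimated by launching
momentum-free overdamped Langevin shots on a model surface and recording
which basin each shot enters first; a point is a transition state when its
Wilson 95% confidence interval overlaps the acceptance band around p = 0.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from ._units import kbt
from .exceptions import ParameterError

#: default candidate-selection tolerances (Å, CN units)
DEFAULT_TOL_DISTANCE = 0.05
DEFAULT_TOL_CN = 0.005

#: default transition-state acceptance band on the committor
DEFAULT_BAND = (0.40, 0.60)

#: timeout fraction above which a warning is emitted
TIMEOUT_WARN_FRACTION = 0.10


def select_candidates(
    cv_series,
    ts_point,
    tol_distance: float = DEFAULT_TOL_DISTANCE,
    tol_cn: float = DEFAULT_TOL_CN,
) -> np.ndarray:
    """Frame indices whose CVs fall within the window around ``ts_point``.

    ``cv_series`` is an (n, 2) array of (distance, CN) pairs or a
    CVTrajectory.  An empty selection is a warning, not an error.
    """
    if tol_distance <= 0 or tol_cn <= 0:
        raise ParameterError("selection tolerances must be positive")
    series = np.asarray(getattr(cv_series, "cvs", cv_series), dtype=float)
    series = series.reshape(-1, 2)
    d0, cn0 = float(ts_point[0]), float(ts_point[1])
    mask = (np.abs(series[:, 0] - d0) <= tol_distance) & (
        np.abs(series[:, 1] - cn0) <= tol_cn
    )
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        warnings.warn("no frames fall inside the selection window", stacklevel=2)
    return idx


@dataclass(frozen=True)
class BasinWindow:
    """Rectangular basin window in CV space."""

    center: tuple[float, float]
    half_widths: tuple[float, float]

    def __post_init__(self):
        if min(self.half_widths) <= 0:
            raise ParameterError("basin half-widths must be positive")

    def contains(self, point) -> bool:
        return (
            abs(point[0] - self.center[0]) <= self.half_widths[0]
            and abs(point[1] - self.center[1]) <= self.half_widths[1]
        )

    def overlaps(self, other: "BasinWindow") -> bool:
        return (
            abs(self.center[0] - other.center[0])
            <= self.half_widths[0] + other.half_widths[0]
            and abs(self.center[1] - other.center[1])
            <= self.half_widths[1] + other.half_widths[1]
        )


def basin_windows_from_minima(rs_point, ps_point, frac: float = 0.3):
    """Basin windows centered on the string's RS/PS minima.

    Half-widths default to ``frac`` × the well separation (isotropically),
    the package's reading of committing "into the equilibrium well".
    """
    rs = np.asarray(rs_point, dtype=float)
    ps = np.asarray(ps_point, dtype=float)
    half = frac * float(np.linalg.norm(ps - rs))
    if half <= 0:
        raise ParameterError("RS and PS minima coincide")
    return (
        BasinWindow(tuple(rs), (half, half)),
        BasinWindow(tuple(ps), (half, half)),
    )


@dataclass
class CommittorResult:
    """Commitment fraction with shot count and Wilson 95% CI."""

    p_product: float
    n_shots: int
    ci95: tuple[float, float]
    outcomes: dict = field(default_factory=dict)
    seed: int = 0
    point: tuple[float, float] | None = None

    def __post_init__(self):
        counted = sum(self.outcomes.values())
        if counted != self.n_shots:
            raise ParameterError("outcome counts must sum to n_shots")
        if not (np.isnan(self.p_product) or 0.0 <= self.p_product <= 1.0):
            raise ParameterError("p_product must lie in [0, 1]")


def estimate_committor(
    surface,
    point,
    basins,
    n_shots: int = 400,
    max_steps: int = 20_000,
    temperature: float = 298.15,
    friction: float = 1.0,
    dt: float = 0.002,
    seed: int = 0,
) -> CommittorResult:
    """Shooting estimate of the committor at ``point``.

    ``basins`` is a (reactant, product) pair of :class:`BasinWindow`; they
    must be disjoint.  Each of the ``n_shots`` overdamped Langevin shots uses
    a distinct sub-seed spawned from ``seed`` and ends on first basin entry
    or after ``max_steps`` (a timeout).  Timeouts are reported separately and
    excluded from p_product, with a warning above 10%.
    """
    reactant, product = basins
    if reactant.overlaps(product):
        raise ParameterError("reactant and product windows overlap")
    if n_shots < 1:
        raise ParameterError("n_shots must be at least 1")
    if dt <= 0 or friction <= 0:
        raise ParameterError("dt and friction must be positive")
    point = np.asarray(point, dtype=float)

    mu = 1.0 / friction
    mu_dt = mu * dt
    noise_scale = np.sqrt(2.0 * mu * kbt(temperature) * dt)
    children = np.random.SeedSequence(seed).spawn(n_shots)

    counts = {"product": 0, "reactant": 0, "timeout": 0}
    for child in children:
        rng = np.random.default_rng(child)
        x = point.copy()
        outcome = "timeout"
        for _ in range(max_steps):
            if reactant.contains(x):
                outcome = "reactant"
                break
            if product.contains(x):
                outcome = "product"
                break
            x = x - mu_dt * surface.gradient(x) + noise_scale * rng.standard_normal(2)
        else:
            if reactant.contains(x):
                outcome = "reactant"
            elif product.contains(x):
                outcome = "product"
        counts[outcome] += 1

    decided = counts["product"] + counts["reactant"]
    if counts["timeout"] > TIMEOUT_WARN_FRACTION * n_shots:
        warnings.warn(
            f"{counts['timeout']}/{n_shots} shots timed out; committor may be "
            "unreliable",
            stacklevel=2,
        )
    if decided == 0:
        warnings.warn("all shots timed out", stacklevel=2)
        p, ci = float("nan"), (0.0, 1.0)
    else:
        p = counts["product"] / decided
        lo, hi = proportion_confint(counts["product"], decided, alpha=0.05,
                                    method="wilson")
        ci = (float(lo), float(hi))
    return CommittorResult(
        p_product=p,
        n_shots=n_shots,
        ci95=ci,
        outcomes=counts,
        seed=seed,
        point=tuple(point),
    )


def is_transition_state(result: CommittorResult, band=DEFAULT_BAND) -> bool:
    """True iff the Wilson 95% CI intersects the acceptance band."""
    lo, hi = result.ci95
    if np.isnan(result.p_product):
        return False
    return lo <= band[1] and hi >= band[0]
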