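"""Zero-temperature string method on a 2-D free-energy surface.

A discretized curve between two basins is relaxed by steepest descent with
equal-arc-length reparameterization after every iteration, converging to the
minimum-energy path (MEP).  The endpoints are not pinned: they descend by the
full gradient and settle into the basin minima.  The FES grid is viewed
through a bicubic spline so values and gradients are continuous across cell
boundaries (descent on bilinear gradients stalls at cell edges).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RectBivariateSpline

from .exceptions import BarrierError, DomainError, NonConvergenceError, ParameterError
from .grids import FESGrid


class FESInterpolator:
    """Bicubic interpolant of a gridded FES with analytic gradients."""

    def __init__(self, fes: FESGrid):
        if fes.x.size < 4 or fes.y.size < 4:
            raise ParameterError("bicubic interpolation needs >= 4 points per axis")
        self._spline = RectBivariateSpline(fes.x, fes.y, fes.values, kx=3, ky=3, s=0)
        self._x, self._y = fes.x, fes.y
        self.bounds = ((fes.x[0], fes.x[-1]), (fes.y[0], fes.y[-1]))
        self.min_spacing = min(fes.spacing)

    def _check(self, pts: np.ndarray) -> None:
        (x0, x1), (y0, y1) = self.bounds
        if (
            np.any(pts[..., 0] < x0)
            or np.any(pts[..., 0] > x1)
            or np.any(pts[..., 1] < y0)
            or np.any(pts[..., 1] > y1)
        ):
            raise DomainError("point outside the FES grid")

    def value(self, pts):
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        self._check(pts)
        v = self._spline.ev(pts[:, 0], pts[:, 1])
        return float(v[0]) if len(v) == 1 else v

    def gradient(self, pts):
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        self._check(pts)
        gx = self._spline.ev(pts[:, 0], pts[:, 1], dx=1)
        gy = self._spline.ev(pts[:, 0], pts[:, 1], dy=1)
        g = np.stack([gx, gy], axis=-1)
        return g[0] if len(g) == 1 else g

    def in_bounds(self, pts) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        (x0, x1), (y0, y1) = self.bounds
        return (
            (pts[:, 0] >= x0)
            & (pts[:, 0] <= x1)
            & (pts[:, 1] >= y0)
            & (pts[:, 1] <= y1)
        )

    def max_curvature(self) -> float:
        """Largest |∂²F/∂x²| + |∂²F/∂y²| over the grid nodes (spline view);
        bounds the stable explicit-descent step 1/κ."""
        xx, yy = np.meshgrid(self._x, self._y, indexing="ij")
        fxx = self._spline.ev(xx.ravel(), yy.ravel(), dx=2)
        fyy = self._spline.ev(xx.ravel(), yy.ravel(), dy=2)
        return float((np.abs(fxx) + np.abs(fyy)).max())


def interpolate(fes: FESGrid, point):
    """Bicubic value and gradient of the FES at ``point`` (inside the grid)."""
    interp = FESInterpolator(fes)
    return interp.value(point), interp.gradient(point)


@dataclass
class StringPath:
    """Ordered images approximating the MEP, with per-image free energies."""

    images: np.ndarray
    energies: np.ndarray
    converged: bool
    iterations: int
    degenerate: bool = False
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=float).reshape(-1, 2)
        self.energies = np.asarray(self.energies, dtype=float)
        if not np.all(np.isfinite(self.energies)):
            raise ParameterError("image energies must be finite")

    @property
    def arc_lengths(self) -> np.ndarray:
        seg = np.linalg.norm(np.diff(self.images, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])


class _SurfaceView:
    """Adapter letting the string run directly on an analytic model surface."""

    def __init__(self, surface):
        self._s = surface
        (x0, x1), (y0, y1) = surface.domain
        self.bounds = surface.domain
        self.min_spacing = min(x1 - x0, y1 - y0) / 200.0

    def value(self, pts):
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        v = np.array([float(self._s.value(p)) for p in pts])
        return float(v[0]) if len(v) == 1 else v

    def gradient(self, pts):
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        g = np.array([self._s.gradient(p) for p in pts])
        return g[0] if len(g) == 1 else g

    def in_bounds(self, pts) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        return np.array([self._s.in_domain(p) for p in pts])

    def max_curvature(self) -> float:
        """Finite-difference estimate of max |Vxx| + |Vyy| over the domain."""
        (x0, x1), (y0, y1) = self.bounds
        x = np.linspace(x0, x1, 101)
        y = np.linspace(y0, y1, 101)
        v = np.asarray(self._s.value((x[:, None], y[None, :])), dtype=float)
        hx, hy = x[1] - x[0], y[1] - y[0]
        fxx = np.abs(np.diff(v, 2, axis=0)).max() / hx**2
        fyy = np.abs(np.diff(v, 2, axis=1)).max() / hy**2
        return float(fxx + fyy)


def _reparameterize(images: np.ndarray, passes: int = 4) -> np.ndarray:
    """Redistribute images to equal arc length along the piecewise-linear path."""
    n = len(images)
    for _ in range(passes):
        seg = np.linalg.norm(np.diff(images, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        if s[-1] == 0.0:
            return images
        target = np.linspace(0.0, s[-1], n)
        images = np.column_stack(
            [np.interp(target, s, images[:, 0]), np.interp(target, s, images[:, 1])]
        )
        seg = np.linalg.norm(np.diff(images, axis=0), axis=1)
        if seg.max() - seg.min() <= 1e-9 * max(seg.mean(), 1e-30):
            break
    return images


def zero_t_string(
    fes,
    start,
    end,
    n_images: int = 30,
    n_steps: int = 3000,
    step_size: float | None = None,
    tol: float = 1e-8,
) -> StringPath:
    """Zero-temperature string method between two CV points.

    Each iteration displaces every image by −∇F·step and reparameterizes the
    string to equal arc length.  ``step_size`` has units CV²·mol/kcal; by
    default the step sits just under the explicit-descent stability limit
    1/κ (κ = largest surface curvature), throttled early on so no image
    moves more than half a grid spacing per iteration — stiff wall modes
    stay stable while soft transverse modes still relax within the default
    3000 iterations.  Images whose trial move
    leaves the grid have their step halved for that move; persistent failure
    raises :class:`NonConvergenceError`.

    ``fes`` may be a :class:`FESGrid` (viewed bicubically) or an analytic
    model surface exposing ``value``/``gradient``/``domain``.
    """
    view = FESInterpolator(fes) if isinstance(fes, FESGrid) else _SurfaceView(fes)
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    for name, p in (("start", start), ("end", end)):
        if not view.in_bounds(p).all():
            raise DomainError(f"{name} point {p} outside the grid")
    if n_images < 2:
        raise ParameterError("need at least 2 images")
    if np.allclose(start, end):
        e = view.value(start)
        return StringPath(
            images=start[None, :],
            energies=np.array([e]),
            converged=True,
            iterations=0,
            degenerate=True,
        )

    t = np.linspace(0.0, 1.0, n_images)[:, None]
    images = (1.0 - t) * start[None, :] + t * end[None, :]
    # default step: just under the stability limit of explicit descent
    # (≈1/κ for the stiffest curvature on the surface); individual image
    # moves are additionally clipped to half a grid spacing per iteration
    cap = 0.5 * view.min_spacing
    if step_size is None:
        kappa = view.max_curvature()
        step = 0.9 / kappa if kappa > 0 else cap
    else:
        step = step_size
    converged = False
    iterations = 0
    for it in range(1, n_steps + 1):
        iterations = it
        grads = view.gradient(images)
        gmax = float(np.abs(grads).max())
        if gmax == 0.0:
            converged = True
            break
        moves = -step * grads
        norms = np.linalg.norm(moves, axis=1)
        big = norms > cap
        if big.any():
            moves[big] *= (cap / norms[big])[:, None]
        trial = images + moves
        # per-image halving for moves that leave the grid
        bad = ~view.in_bounds(trial)
        halvings = 0
        while bad.any():
            halvings += 1
            if halvings > 60:
                raise NonConvergenceError(
                    f"images {np.flatnonzero(bad).tolist()} cannot move "
                    "without leaving the grid"
                )
            trial[bad] = images[bad] + 0.5 * (trial[bad] - images[bad])
            bad = ~view.in_bounds(trial)
        new_images = _reparameterize(trial)
        displacement = float(np.abs(new_images - images).max())
        images = new_images
        if displacement < tol:
            converged = True
            break
    # final tightening so consecutive arc-length spacings agree to ~1e-9
    images = _reparameterize(images, passes=40)
    energies = view.value(images)
    return StringPath(
        images=images,
        energies=np.atleast_1d(energies),
        converged=converged,
        iterations=iterations,
        metadata={"n_images": n_images, "n_steps": n_steps},
    )


def barrier(path: StringPath) -> dict:
    """Activation free energy and stationary points of a string path.

    ΔG‡ is the maximum image energy (parabolically refined across the three
    highest images in arc length) minus the reactant-side minimum — not the
    global minimum, so an exergonic product well does not inflate the barrier.
    """
    if path.degenerate or len(path.images) < 3:
        raise BarrierError("path is degenerate; no barrier defined")
    e = path.energies
    m = int(np.argmax(e))
    if m == 0 or m == len(e) - 1:
        raise BarrierError("no barrier on path (maximum at an endpoint)")
    span = float(e.max() - e.min())
    if span < 1e-12:
        raise BarrierError("no barrier on path (flat energy profile)")
    s = path.arc_lengths
    # parabolic refinement through the three highest images
    s3, e3 = s[m - 1 : m + 2], e[m - 1 : m + 2]
    coeffs = np.polyfit(s3, e3, 2)
    if coeffs[0] < 0:
        s_ts = -coeffs[1] / (2.0 * coeffs[0])
        s_ts = float(np.clip(s_ts, s3[0], s3[2]))
        e_ts = float(np.polyval(coeffs, s_ts))
    else:  # degenerate curvature; keep the discrete maximum
        s_ts, e_ts = float(s[m]), float(e[m])
    ts_point = np.array(
        [np.interp(s_ts, s, path.images[:, 0]), np.interp(s_ts, s, path.images[:, 1])]
    )
    i_rs = int(np.argmin(e[: m + 1]))
    i_ps = m + int(np.argmin(e[m:]))
    return {
        "delta_g": e_ts - float(e[i_rs]),
        "ts_point": ts_point,
        "ts_energy": e_ts,
        "rs_point": path.images[i_rs].copy(),
        "rs_energy": float(e[i_rs]),
        "ps_point": path.images[i_ps].copy(),
        "ps_energy": float(e[i_ps]),
    }
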