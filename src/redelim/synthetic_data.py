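"""Synthetic model systems with analytically known ground truth.

Desk-scale stand-ins for ab initio molecular dynamics: model potentials in
2-D collective-variable space, overdamped Langevin dynamics, well-tempered
metadynamics hill streams, and grouped point-charge environments around a
two-bond probe substrate.  Every stochastic operation is reproducible from
its seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from ._units import COULOMB_MV_CM, kbt
from .exceptions import DomainEscapeError, ParameterError
from .io import HillList


# ---------------------------------------------------------------------------
# Model surfaces

class ModelSurface:
    """Analytic potential V(x, y) on a rectangular domain (kcal/mol).

    Subclasses provide ``value`` and ``gradient``; ``stationary_points``
    lists points where the gradient vanishes (used as test oracles).
    """

    domain: tuple[tuple[float, float], tuple[float, float]]
    stationary_points: list

    def value(self, point):
        raise NotImplementedError

    def gradient(self, point):
        raise NotImplementedError

    def in_domain(self, point) -> bool:
        (x0, x1), (y0, y1) = self.domain
        return x0 <= point[0] <= x1 and y0 <= point[1] <= y1


@dataclass
class DoubleWellSurface(ModelSurface):
    """V(x, y) = h[(x/a)² − 1]² + ½ k y² + tilt·(x/a).

    Minima near (±a, 0) with V = 0 there (exactly, for tilt = 0); saddle near
    (0, 0) with V = h.  ``tilt`` adds a linear asymmetry so the two wells sit
    at different energies.
    """

    h: float
    a: float
    k: float
    tilt: float = 0.0

    def __post_init__(self):
        if self.h <= 0 or self.a <= 0 or self.k <= 0:
            raise ParameterError("h, a and k must all be positive")
        self.domain = ((-3 * self.a, 3 * self.a), (-3.0, 3.0))
        self.stationary_points = [
            np.array([-self.a, 0.0]),
            np.array([0.0, 0.0]),
            np.array([self.a, 0.0]),
        ] if self.tilt == 0.0 else []

    def value(self, point):
        u = np.asarray(point[0]) / self.a
        y = np.asarray(point[1])
        return self.h * (u * u - 1.0) ** 2 + 0.5 * self.k * y**2 + self.tilt * u

    def gradient(self, point):
        x, y = float(point[0]), float(point[1])
        u = x / self.a
        gx = (4.0 * self.h * u * (u * u - 1.0) + self.tilt) / self.a
        gy = self.k * y
        return np.array([gx, gy])


@dataclass
class HarmonicSurface(ModelSurface):
    """V(x, y) = ½ kx x² + ½ ky y², minimum at the origin."""

    kx: float = 1.0
    ky: float = 1.0

    def __post_init__(self):
        if self.kx <= 0 or self.ky <= 0:
            raise ParameterError("stiffnesses must be positive")
        self.domain = ((-50.0, 50.0), (-50.0, 50.0))
        self.stationary_points = [np.array([0.0, 0.0])]

    def value(self, point):
        return 0.5 * self.kx * np.asarray(point[0]) ** 2 \
            + 0.5 * self.ky * np.asarray(point[1]) ** 2

    def gradient(self, point):
        return np.array([self.kx * float(point[0]), self.ky * float(point[1])])


def make_double_well(h: float, a: float, k: float, tilt: float = 0.0) -> DoubleWellSurface:
    """Symmetric (or tilted) double well with barrier h (kcal/mol), wells at
    ±a in CV1 and transverse stiffness k."""
    return DoubleWellSurface(h=h, a=a, k=k, tilt=tilt)


# ---------------------------------------------------------------------------
# Trajectories

@dataclass
class CVTrajectory:
    """Time series of 2-D CV values from a stochastic run.

    ``cvs[i]`` is the (cv1, cv2) pair at ``times[i]``; times are fs with a
    constant step, length n_steps + 1.
    """

    times: np.ndarray
    cvs: np.ndarray
    seed: int
    temperature: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.cvs = np.asarray(self.cvs, dtype=float).reshape(-1, 2)
        if len(self.times) != len(self.cvs):
            raise ParameterError("times/cvs length mismatch")
        if len(self.times) > 1:
            dt = np.diff(self.times)
            if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-9):
                raise ParameterError("times must increase with a constant step")

    @property
    def cv1(self) -> np.ndarray:
        return self.cvs[:, 0]

    @property
    def cv2(self) -> np.ndarray:
        return self.cvs[:, 1]

    def __len__(self) -> int:
        return len(self.times)


class _GaussianBias:
    """Growing sum of 2-D Gaussians with fast value/gradient evaluation."""

    def __init__(self, capacity: int = 0):
        self.centers = np.empty((max(capacity, 8), 2))
        self.widths = np.empty((max(capacity, 8), 2))
        self.heights = np.empty(max(capacity, 8))
        self.n = 0

    @classmethod
    def from_hills(cls, hills: HillList) -> "_GaussianBias":
        b = cls(len(hills))
        b.centers[: len(hills)] = hills.centers
        b.widths[: len(hills)] = hills.widths
        b.heights[: len(hills)] = hills.heights
        b.n = len(hills)
        return b

    def add(self, center, widths, height) -> None:
        if self.n == len(self.heights):
            grow = max(8, self.n)
            self.centers = np.vstack([self.centers, np.empty((grow, 2))])
            self.widths = np.vstack([self.widths, np.empty((grow, 2))])
            self.heights = np.concatenate([self.heights, np.empty(grow)])
        self.centers[self.n] = center
        self.widths[self.n] = widths
        self.heights[self.n] = height
        self.n += 1

    def value(self, point) -> float:
        if self.n == 0:
            return 0.0
        d = (point - self.centers[: self.n]) / self.widths[: self.n]
        return float(
            np.dot(self.heights[: self.n], np.exp(-0.5 * (d * d).sum(axis=1)))
        )

    def gradient(self, point) -> np.ndarray:
        if self.n == 0:
            return np.zeros(2)
        d = (point - self.centers[: self.n]) / self.widths[: self.n]
        w = self.heights[: self.n] * np.exp(-0.5 * (d * d).sum(axis=1))
        return -(w[:, None] * d / self.widths[: self.n]).sum(axis=0)


def langevin_trajectory(
    surface: ModelSurface,
    start,
    *,
    temperature: float = 298.15,
    friction: float = 1.0,
    dt: float = 0.01,
    n_steps: int = 1000,
    seed: int = 0,
    bias: HillList | None = None,
) -> CVTrajectory:
    """Overdamped (first-order) Langevin trajectory on a model surface.

    Euler–Maruyama update x ← x − μ ∇V dt + √(2 μ k_BT dt) ξ with mobility
    μ = 1/friction (friction in fs⁻¹, dt in fs).  Identical seeds give
    bitwise-identical trajectories.  An optional fixed metadynamics bias
    (a :class:`~redelim.io.HillList`) is added to the potential.
    """
    if dt <= 0 or friction <= 0:
        raise ParameterError("dt and friction must be positive")
    if n_steps < 0:
        raise ParameterError("n_steps must be non-negative")
    if not surface.in_domain(start):
        raise ParameterError(f"start {start} outside surface domain")
    mu = 1.0 / friction
    noise_scale = math.sqrt(2.0 * mu * kbt(temperature) * dt)
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((n_steps, 2)) * noise_scale
    bias_sum = _GaussianBias.from_hills(bias) if bias is not None else None

    out = np.empty((n_steps + 1, 2))
    x = np.array(start, dtype=float)
    out[0] = x
    mu_dt = mu * dt
    for i in range(n_steps):
        g = surface.gradient(x)
        if bias_sum is not None:
            g = g + bias_sum.gradient(x)
        x = x - mu_dt * g + noise[i]
        if not surface.in_domain(x):
            partial = CVTrajectory(
                times=np.arange(i + 1) * dt,
                cvs=out[: i + 1].copy(),
                seed=seed,
                temperature=temperature,
            )
            raise DomainEscapeError(
                f"trajectory left the domain at step {i + 1} (point {x})",
                last_valid=partial,
            )
        out[i + 1] = x
    return CVTrajectory(
        times=np.arange(n_steps + 1) * dt,
        cvs=out,
        seed=seed,
        temperature=temperature,
        metadata={"dt_fs": dt, "friction_inv_fs": friction},
    )


def run_metadynamics(
    surface: ModelSurface,
    *,
    height: float = 3.1375,
    pace: int = 30,
    widths=(0.1, 0.25),
    bias_factor: float = 15.0,
    temperature: float = 298.15,
    friction: float = 100.0,
    dt: float = 0.5,
    n_steps: int = 100_000,
    seed: int = 0,
    start=None,
    min_crossings: int | None = None,
    max_steps: int | None = None,
    dividing: float = 0.0,
    hysteresis: float = 0.2,
    wall_stiffness: float = 100.0,
    wall_margin: float = 0.15,
) -> tuple[CVTrajectory, HillList]:
    """Well-tempered metadynamics with the overdamped Langevin stand-in.

    One Gaussian of nominal ``height`` (kcal/mol) is deposited every ``pace``
    steps (fixed-pace reading of an at-least-every-30-steps schedule); with a
    finite bias factor γ the deposited height is damped by
    exp(−V_B/(k_B ΔT)), ΔT = (γ−1)T.  Pass ``bias_factor=math.inf`` for
    standard (undamped) metadynamics.

    If ``min_crossings`` is given, the run is extended beyond ``n_steps``
    (in whole-pace chunks, up to ``max_steps``) until the CV1 series has
    committed across ``dividing`` at least that many times under the
    hysteresis rule — mirroring a run-until-the-barrier-is-crossed protocol.

    Because the accumulating bias would otherwise push the walker out of the
    declared CV domain, harmonic restraining walls (stiffness
    ``wall_stiffness`` kcal/mol per CV-unit²) act beyond an inner margin of
    ``wall_margin`` × the domain extent from each edge; set
    ``wall_stiffness=0`` to disable them.
    """
    from .fes import count_crossings  # local import; fes also imports io

    if pace < 1:
        raise ParameterError("pace must be >= 1")
    widths = np.asarray(widths, dtype=float)
    if widths.shape != (2,) or np.any(widths <= 0):
        raise ParameterError("two positive hill widths required")
    if height <= 0:
        raise ParameterError("hill height must be positive")
    if not math.isinf(bias_factor) and bias_factor <= 1:
        raise ParameterError("bias factor must exceed 1 (ΔT = (γ-1)T > 0)")
    if dt <= 0 or friction <= 0:
        raise ParameterError("dt and friction must be positive")
    if start is None:
        mins = [p for p in getattr(surface, "stationary_points", [])
                if p[0] < dividing]
        start = mins[0] if mins else np.zeros(2)
    if not surface.in_domain(start):
        raise ParameterError(f"start {start} outside surface domain")
    if max_steps is None:
        max_steps = n_steps if min_crossings is None else 4 * n_steps
    n_steps = (n_steps // pace) * pace or pace

    mu = 1.0 / friction
    kt = kbt(temperature)
    damping_kt = None if math.isinf(bias_factor) else (bias_factor - 1.0) * kt
    noise_scale = math.sqrt(2.0 * mu * kt * dt)
    rng = np.random.default_rng(seed)
    bias_sum = _GaussianBias(capacity=max_steps // pace + 1)

    (x0, x1), (y0, y1) = surface.domain
    lo = np.array([x0, y0])
    hi = np.array([x1, y1])
    margin = wall_margin * (hi - lo)
    wall_lo, wall_hi = lo + margin, hi - margin

    def wall_gradient(p):
        g = np.zeros(2)
        over = p - wall_hi
        under = wall_lo - p
        g[over > 0] += wall_stiffness * over[over > 0]
        g[under > 0] -= wall_stiffness * under[under > 0]
        return g

    mu_dt = mu * dt
    x = np.array(start, dtype=float)
    traj = [x.copy()]
    hill_times = []
    step = 0
    while True:
        # advance one pace-chunk
        noise = rng.standard_normal((pace, 2)) * noise_scale
        for i in range(pace):
            g = surface.gradient(x) + bias_sum.gradient(x)
            if wall_stiffness > 0:
                g = g + wall_gradient(x)
            x = x - mu_dt * g + noise[i]
            if not surface.in_domain(x):
                partial = CVTrajectory(
                    times=np.arange(len(traj)) * dt,
                    cvs=np.array(traj),
                    seed=seed,
                    temperature=temperature,
                )
                raise DomainEscapeError(
                    f"metadynamics walker left the domain at step "
                    f"{step + i + 1} (point {x})",
                    last_valid=partial,
                )
            traj.append(x.copy())
        step += pace
        # deposit
        if damping_kt is None:
            h = height
        else:
            h = height * math.exp(-bias_sum.value(x) / damping_kt)
        bias_sum.add(x, widths, h)
        hill_times.append(step * dt)
        if step >= n_steps:
            if min_crossings is None:
                break
            cv1 = np.array(traj)[:, 0]
            if count_crossings(cv1, dividing, hysteresis) >= min_crossings:
                break
            if step + pace > max_steps:
                warnings.warn(
                    f"reached max_steps={max_steps} with fewer than "
                    f"{min_crossings} crossings",
                    stacklevel=2,
                )
                break

    trajectory = CVTrajectory(
        times=np.arange(len(traj)) * dt,
        cvs=np.array(traj),
        seed=seed,
        temperature=temperature,
        metadata={
            "dt_fs": dt,
            "friction_inv_fs": friction,
            "pace": pace,
            "nominal_height_kcal": height,
            "bias_factor": bias_factor,
        },
    )
    nh = bias_sum.n
    hills = HillList(
        times=np.array(hill_times),
        centers=bias_sum.centers[:nh].copy(),
        widths=bias_sum.widths[:nh].copy(),
        heights=bias_sum.heights[:nh].copy(),
        bias_factor=bias_factor,
    )
    return trajectory, hills


# ---------------------------------------------------------------------------
# Point-charge environments

@dataclass
class BondProbe:
    """A probe bond (Au → C): fields are evaluated at the bond midpoint and
    projected on the Au→C unit vector."""

    au_pos: np.ndarray
    c_pos: np.ndarray

    def __post_init__(self):
        self.au_pos = np.asarray(self.au_pos, dtype=float)
        self.c_pos = np.asarray(self.c_pos, dtype=float)
        if np.allclose(self.au_pos, self.c_pos):
            raise ParameterError("probe bond has zero length")

    @property
    def midpoint(self) -> np.ndarray:
        return 0.5 * (self.au_pos + self.c_pos)

    @property
    def unit(self) -> np.ndarray:
        v = self.c_pos - self.au_pos
        return v / np.linalg.norm(v)

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.c_pos - self.au_pos))


GROUP_NAMES = ("bulk_water", "complexed_water", "cage")

#: minimum allowed charge–probe distance (Å)
PROBE_EXCLUSION = 0.5


@dataclass
class PointChargeEnvironment:
    """Named groups of point charges around a two-bond probe substrate.

    ``groups`` maps a group name to (charges [e], positions [Å, shape (n,3)]).
    Every charge belongs to exactly one group; no charge may sit within
    0.5 Å of a probe midpoint.
    """

    groups: dict
    probes: tuple[BondProbe, BondProbe]

    def __post_init__(self):
        for name, (q, pos) in self.groups.items():
            q = np.asarray(q, dtype=float)
            pos = np.asarray(pos, dtype=float).reshape(-1, 3)
            if len(q) != len(pos):
                raise ParameterError(f"group {name!r}: charge/position mismatch")
            for probe in self.probes:
                if len(pos) and np.min(
                    np.linalg.norm(pos - probe.midpoint, axis=1)
                ) <= PROBE_EXCLUSION:
                    raise ParameterError(
                        f"group {name!r} has a charge within {PROBE_EXCLUSION} Å "
                        "of a probe point"
                    )
            self.groups[name] = (q, pos)


def _coulomb_field_at(point, charges, positions) -> np.ndarray:
    """Direct Coulomb sum, MV/cm: E = Σ k q (r−r_i)/|r−r_i|³ (loop oracle)."""
    e = np.zeros(3)
    for q, p in zip(charges, positions):
        d = point - p
        r = math.sqrt(float(d @ d))
        e += COULOMB_MV_CM * q * d / r**3
    return e


def make_charge_environment(spec: dict | None = None, seed: int = 0):
    """Build a grouped point-charge environment plus per-group ground truth.

    ``spec`` maps each group name to either an explicit charge set
    ``{"charges": [...], "positions": [[x,y,z], ...]}`` or a shell recipe
    ``{"kind": "water_shell"|"charged_shell", ...}``; missing groups are
    empty (with a warning).  The default spec emulates the catalyzed scene:
    a bulk-water shell of point dipolar waters, one complexed water molecule
    near the substrate, and a 12× (−1 e) anionic shell for the nanocage.

    Returns ``(environment, ground_truth)`` where ``ground_truth[group]`` is
    the (bond-1, bond-2) pair of projected fields in MV/cm obtained by direct
    Coulomb summation — the analytic reference the efield module is tested
    against.
    """
    rng = np.random.default_rng(seed)
    # substrate: Au at origin, two probe carbons 2.1 Å away, ~90° apart
    au = np.zeros(3)
    c1 = np.array([2.1, 0.0, 0.0])
    c2 = np.array([0.0, 2.1, 0.0])
    probes = (BondProbe(au, c1), BondProbe(au, c2))

    if spec is None:
        spec = default_charge_spec()

    groups = {}
    for name in GROUP_NAMES:
        gspec = spec.get(name)
        if not gspec:
            warnings.warn(f"group {name!r} is empty; zero field recorded",
                          stacklevel=2)
            groups[name] = (np.empty(0), np.empty((0, 3)))
            continue
        if "charges" in gspec:
            q = np.asarray(gspec["charges"], dtype=float)
            pos = np.asarray(gspec["positions"], dtype=float).reshape(-1, 3)
        elif gspec.get("kind") == "water_shell":
            q, pos = _water_shell(
                rng,
                n_waters=gspec.get("n_waters", 40),
                r_min=gspec.get("r_min", 6.0),
                r_max=gspec.get("r_max", 12.0),
            )
        elif gspec.get("kind") == "single_water":
            q, pos = _single_water(rng, distance=gspec.get("distance", 3.2))
        elif gspec.get("kind") == "charged_shell":
            q, pos = _charged_shell(
                rng,
                n=gspec.get("n", 12),
                charge=gspec.get("charge", -1.0),
                radius=gspec.get("radius", 7.0),
            )
        else:
            raise ParameterError(f"group {name!r}: unrecognized spec {gspec}")
        groups[name] = (q, pos)

    env = PointChargeEnvironment(groups=groups, probes=probes)
    ground_truth = {}
    for name, (q, pos) in env.groups.items():
        fields = []
        for probe in env.probes:
            if len(q) == 0:
                fields.append(0.0)
            else:
                e = _coulomb_field_at(probe.midpoint, q, pos)
                fields.append(float(e @ probe.unit))
        ground_truth[name] = tuple(fields)
    return env, ground_truth


def default_charge_spec() -> dict:
    """Three-group scene: bulk solvent shell, one complexed water, anionic cage."""
    return {
        "bulk_water": {"kind": "water_shell", "n_waters": 40,
                       "r_min": 8.0, "r_max": 14.0},
        "complexed_water": {"kind": "single_water", "distance": 3.2},
        "cage": {"kind": "charged_shell", "n": 12, "charge": -1.0, "radius": 7.0},
    }


_TIP3P = (-0.834, 0.417, 0.417)


def _water_geometry(rng, origin) -> tuple[np.ndarray, np.ndarray]:
    """TIP3P-like 3-point water with random orientation at ``origin``."""
    # O at origin; H at 0.9572 Å, HOH angle 104.52 deg, then random rotation
    ang = math.radians(104.52) / 2
    local = np.array(
        [
            [0.0, 0.0, 0.0],
            [0.9572 * math.cos(ang), 0.9572 * math.sin(ang), 0.0],
            [0.9572 * math.cos(ang), -0.9572 * math.sin(ang), 0.0],
        ]
    )
    # random rotation via QR of a Gaussian matrix
    m = rng.standard_normal((3, 3))
    qmat, r = np.linalg.qr(m)
    qmat *= np.sign(np.diag(r))
    return np.array(_TIP3P), local @ qmat.T + origin


def _random_unit(rng) -> np.ndarray:
    v = rng.standard_normal(3)
    return v / np.linalg.norm(v)


def _water_shell(rng, n_waters, r_min, r_max):
    qs, ps = [], []
    for _ in range(n_waters):
        r = (r_min**3 + (r_max**3 - r_min**3) * rng.random()) ** (1.0 / 3.0)
        q, pos = _water_geometry(rng, r * _random_unit(rng))
        qs.append(q)
        ps.append(pos)
    return np.concatenate(qs), np.vstack(ps)


def _single_water(rng, distance):
    # placed near the bisector of the two probe bonds, like a vicinal water
    direction = np.array([1.0, 1.0, 0.6])
    direction /= np.linalg.norm(direction)
    return _water_geometry(rng, distance * direction)


def _charged_shell(rng, n, charge, radius):
    qs = np.full(n, charge)
    ps = np.vstack([radius * _random_unit(rng) for _ in range(n)])
    return qs, ps
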