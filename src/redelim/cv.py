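"""Collective variables for the reductive-elimination reaction.

Two CVs span the reaction space: the distance between the carbons of the two
leaving methyl groups, and a smooth coordination number between the gold atom
and those two carbons built from the rational switching function

    CN = 1/2 * sum_i [1 - (r_i/R0)^p] / [1 - (r_i/R0)^q],   p=8, q=14,

which is continuous at r = R0 with the removable-singularity limit p/q.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ParameterError

#: guard band around r = R0 inside which the analytic limit p/q is used
_R0_GUARD = 1e-9


@dataclass(frozen=True)
class CNParams:
    """Parameters of the rational switching function.

    r0 is the reference (equilibrium) Au–C distance in Å; p and q are the
    numerator/denominator exponents (0 < p < q).
    """

    r0: float = 2.1
    p: int = 8
    q: int = 14

    def __post_init__(self):
        if self.r0 <= 0:
            raise ParameterError("R0 must be positive")
        if not (0 < self.p < self.q):
            raise ParameterError("exponents must satisfy 0 < p < q")


@dataclass
class Frame:
    """One Cartesian frame: atom labels plus coordinates in Å."""

    labels: list[str]
    coords: np.ndarray
    index: int = 0

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ParameterError("coords must have shape (n_atoms, 3)")
        if len(self.labels) != self.coords.shape[0]:
            raise ParameterError("label/coordinate count mismatch")
        if not np.all(np.isfinite(self.coords)):
            raise ParameterError(f"non-finite coordinates in frame {self.index}")


def methyl_distance(frame: Frame, c1: int, c2: int) -> float:
    """Distance (Å) between the two leaving-methyl carbons."""
    if c1 == c2:
        raise ParameterError("carbon indices must be distinct")
    d = float(np.linalg.norm(frame.coords[c1] - frame.coords[c2]))
    if d == 0.0:
        warnings.warn(
            f"degenerate geometry: atoms {c1} and {c2} coincide in frame "
            f"{frame.index}",
            stacklevel=2,
        )
    return d


def switching_term(r, params: CNParams = CNParams()):
    """Rational switching value [1-(r/R0)^p]/[1-(r/R0)^q], elementwise.

    At r = R0 (within a 1e-9 relative guard band) the removable singularity
    is evaluated analytically as p/q.
    """
    t = np.asarray(r, dtype=float) / params.r0
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    near = np.abs(t - 1.0) < _R0_GUARD
    safe = np.where(near, 2.0, t)  # placeholder value, overwritten below
    out = (1.0 - safe**params.p) / (1.0 - safe**params.q)
    out[near] = params.p / params.q
    return float(out[0]) if scalar else out


def coordination_number(
    frame: Frame,
    au: int,
    carbons: tuple[int, int],
    params: CNParams = CNParams(),
) -> float:
    """Au–C coordination number of the two leaving-methyl carbons."""
    c1, c2 = carbons
    if len({au, c1, c2}) != 3:
        raise ParameterError("gold and carbon indices must be distinct")
    r = np.linalg.norm(frame.coords[[c1, c2]] - frame.coords[au], axis=1)
    return float(0.5 * np.sum(switching_term(r, params)))


def cv_series(
    frames,
    au: int,
    carbons: tuple[int, int],
    params: CNParams = CNParams(),
) -> np.ndarray:
    """(n_frames, 2) array of (methyl–methyl distance, coordination number)."""
    out = np.empty((len(frames), 2))
    for i, f in enumerate(frames):
        out[i, 0] = methyl_distance(f, *carbons)
        out[i, 1] = coordination_number(f, au, carbons, params)
    return out
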