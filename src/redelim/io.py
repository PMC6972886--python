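"""File formats: HILLS streams, XYZ trajectories, snapshot tables, FES grids.

The canonical on-disk hills dialect follows the PLUMED column order
(time, cv1, cv2, sigma1, sigma2, height, biasf).  A ``cp2k`` dialect flag
accepts the same layout with heights in Hartree, converted to kcal/mol on
read.  All readers reject malformed input rather than silently repairing it,
and every writer produces files its paired reader accepts bit-compatibly.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from ._units import KCAL_PER_HARTREE
from .cv import Frame
from .exceptions import HillsFormatError, ParameterError, SchemaError
from .grids import FESGrid

_HILLS_FIELDS = "time cv1 cv2 sigma_cv1 sigma_cv2 height biasf"


@dataclass(frozen=True)
class HillRecord:
    """One deposited Gaussian in 2-D CV space (height in kcal/mol)."""

    time: float
    center: tuple[float, float]
    widths: tuple[float, float]
    height: float
    bias_factor: float = math.inf

    def __post_init__(self):
        if min(self.widths) <= 0:
            raise ParameterError("hill widths must be positive")
        if self.height < 0:
            raise ParameterError("hill height must be non-negative")


class HillList:
    """Ordered record of the biasing history.

    Stores times (fs), centers, per-CV widths and heights (kcal/mol) as
    arrays; ``bias_factor`` is the well-tempered γ (``inf`` sentinel for
    standard metadynamics).
    """

    def __init__(self, times, centers, widths, heights, bias_factor=math.inf):
        self.times = np.asarray(times, dtype=float)
        self.centers = np.asarray(centers, dtype=float).reshape(-1, 2)
        self.widths = np.asarray(widths, dtype=float).reshape(-1, 2)
        self.heights = np.asarray(heights, dtype=float)
        self.bias_factor = float(bias_factor)
        n = len(self.times)
        if not (len(self.centers) == len(self.widths) == len(self.heights) == n):
            raise ParameterError("hill arrays must have equal length")
        if n and np.any(np.diff(self.times) < 0):
            raise ParameterError("hill times must be non-decreasing")
        if np.any(self.widths <= 0):
            raise ParameterError("hill widths must be positive")
        if np.any(self.heights < 0):
            raise ParameterError("hill heights must be non-negative")

    @classmethod
    def empty(cls, bias_factor=math.inf) -> "HillList":
        return cls(np.empty(0), np.empty((0, 2)), np.empty((0, 2)), np.empty(0),
                   bias_factor)

    def __len__(self) -> int:
        return len(self.times)

    def __getitem__(self, i: int) -> HillRecord:
        return HillRecord(
            time=float(self.times[i]),
            center=tuple(self.centers[i]),
            widths=tuple(self.widths[i]),
            height=float(self.heights[i]),
            bias_factor=self.bias_factor,
        )

    def __iter__(self):
        return (self[i] for i in range(len(self)))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "cv1": self.centers[:, 0],
                "cv2": self.centers[:, 1],
                "sigma_cv1": self.widths[:, 0],
                "sigma_cv2": self.widths[:, 1],
                "height": self.heights,
                "biasf": np.full(len(self), self.bias_factor),
            }
        )


def write_hills(hills: HillList, path) -> None:
    """Write a PLUMED-style HILLS file (energies in kcal/mol)."""
    with open(path, "w") as fh:
        fh.write(f"#! FIELDS {_HILLS_FIELDS}\n")
        fh.write("#! SET energy_unit kcal/mol\n")
        for h in hills:
            fh.write(
                "%.17g %.17g %.17g %.17g %.17g %.17g %.17g\n"
                % (h.time, *h.center, *h.widths, h.height, hills.bias_factor)
            )


def read_hills(path, dialect: str = "plumed") -> HillList:
    """Read a hills file.

    ``plumed``: heights in the unit declared by the ``energy_unit`` header
    (default kcal/mol).  ``cp2k``: same column layout, heights in Hartree,
    converted to kcal/mol on read.
    """
    if dialect not in ("plumed", "cp2k"):
        raise ParameterError(f"unknown hills dialect {dialect!r}")
    scale = KCAL_PER_HARTREE if dialect == "cp2k" else 1.0
    rows = []
    bias_factor = math.inf
    last_t = -math.inf
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("#! SET energy_unit") and dialect == "plumed":
                    unit = line.split()[-1]
                    if unit == "hartree":
                        scale = KCAL_PER_HARTREE
                    elif unit != "kcal/mol":
                        raise HillsFormatError(
                            f"line {lineno}: unsupported energy_unit {unit!r}"
                        )
                continue
            parts = line.split()
            if len(parts) != 7:
                raise HillsFormatError(
                    f"line {lineno}: expected 7 columns, got {len(parts)}"
                )
            try:
                t, c1, c2, s1, s2, h, bf = (float(p) for p in parts)
            except ValueError as exc:
                raise HillsFormatError(f"line {lineno}: {exc}") from None
            if t < last_t:
                raise HillsFormatError(
                    f"line {lineno}: time {t} decreases below {last_t}"
                )
            if s1 <= 0 or s2 <= 0:
                raise HillsFormatError(f"line {lineno}: non-positive width")
            if h < 0:
                raise HillsFormatError(f"line {lineno}: negative height")
            last_t = t
            bias_factor = bf
            rows.append((t, c1, c2, s1, s2, h * scale))
    if not rows:
        return HillList.empty()
    arr = np.array(rows)
    return HillList(arr[:, 0], arr[:, 1:3], arr[:, 3:5], arr[:, 5], bias_factor)


# ---------------------------------------------------------------------------
# XYZ trajectories

def _scan_xyz_structure(path: str) -> None:
    """Validate the frame structure of an XYZ file (atom counts, truncation)."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    pos = 0
    frame = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            n_atoms = int(lines[pos].strip())
        except ValueError:
            raise HillsFormatError(
                f"frame {frame}: expected an atom count, got {lines[pos]!r}"
            ) from None
        body = lines[pos + 2 : pos + 2 + n_atoms]
        if len(body) < n_atoms or any(len(ln.split()) < 4 for ln in body):
            raise HillsFormatError(
                f"frame {frame}: atom count mismatch ({n_atoms} declared)"
            )
        pos += 2 + n_atoms
        frame += 1


def read_xyz(path) -> list[Frame]:
    """Read a (multi-frame) XYZ file into a list of :class:`~redelim.cv.Frame`.

    A structural pre-scan rejects truncated or miscounted frames (naming the
    frame index) rather than silently repairing them; numeric parsing is then
    delegated to MDAnalysis.
    """
    import MDAnalysis as mda

    path = str(path)
    _scan_xyz_structure(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # mass/element guessing chatter
        u = mda.Universe(path, format="XYZ", topology_format="XYZ")
        labels = [str(n) for n in u.atoms.names]
        frames = []
        try:
            for i, _ts in enumerate(u.trajectory):
                frames.append(
                    Frame(labels=labels, coords=u.atoms.positions.copy(), index=i)
                )
        except (ValueError, EOFError) as exc:
            raise HillsFormatError(
                f"malformed XYZ frame {len(frames)} in {path}: {exc}"
            ) from exc
    return frames


def write_xyz(frames, path, comment: str = "") -> None:
    """Write frames to a plain XYZ file."""
    with open(path, "w") as fh:
        for f in frames:
            fh.write(f"{len(f.labels)}\n{comment or f'frame {f.index}'}\n")
            for lab, (x, y, z) in zip(f.labels, f.coords):
                fh.write(f"{lab} {x:.10f} {y:.10f} {z:.10f}\n")


# ---------------------------------------------------------------------------
# Snapshot tables (per-state, per-bond projected fields and bond dipoles)

SNAPSHOT_REQUIRED = ["state", "bond", "group", "field_MV_cm", "dipole_D"]
SNAPSHOT_OPTIONAL = ["reaction", "q_au_e", "q_c_e", "d_A"]
_STATES = ("RS", "TS")
_BONDS = (1, 2)


class SnapshotTable:
    """Long-format table of projected fields (MV/cm) and bond dipoles (Debye).

    Rows are keyed by (reaction, state ∈ {RS, TS}, bond ∈ {1, 2}, group).
    The dipole is a per-(state, bond) quantity repeated across group rows;
    the reader validates that the repeats agree.  Missing groups are recorded
    as absent, not as zero.
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in SNAPSHOT_REQUIRED if c not in df.columns]
        if missing:
            raise SchemaError(f"snapshot table missing columns: {missing}")
        df = df.copy()
        if "reaction" not in df.columns:
            df["reaction"] = "default"
        df["bond"] = df["bond"].astype(int)
        bad_states = set(df["state"]) - set(_STATES)
        if bad_states:
            raise SchemaError(f"unknown states {sorted(bad_states)}")
        if not set(df["bond"]).issubset(_BONDS):
            raise SchemaError("bond indices must be 1 or 2")
        dup = df.duplicated(["reaction", "state", "bond", "group"])
        if dup.any():
            raise SchemaError("duplicate (reaction, state, bond, group) rows")
        for key, sub in df.groupby(["reaction", "state", "bond"]):
            if sub["dipole_D"].nunique() > 1:
                raise SchemaError(f"inconsistent dipole for {key}")
        self.df = df

    @classmethod
    def from_csv(cls, path) -> "SnapshotTable":
        return cls(pd.read_csv(path, comment="#"))

    def reactions(self) -> list[str]:
        return sorted(self.df["reaction"].unique())

    def groups(self, reaction=None) -> list[str]:
        df = self._select(reaction)
        return sorted(df["group"].unique())

    def _select(self, reaction) -> pd.DataFrame:
        if reaction is None:
            if len(self.reactions()) > 1:
                raise SchemaError(
                    "table holds several reactions; specify one of "
                    f"{self.reactions()}"
                )
            return self.df
        sub = self.df[self.df["reaction"] == reaction]
        if sub.empty:
            raise SchemaError(f"no rows for reaction {reaction!r}")
        return sub

    def field(self, state: str, bond: int, group: str, reaction=None) -> float:
        sub = self._select(reaction)
        row = sub[
            (sub["state"] == state) & (sub["bond"] == bond) & (sub["group"] == group)
        ]
        if row.empty:
            raise SchemaError(f"missing field row ({state}, {bond}, {group})")
        return float(row["field_MV_cm"].iloc[0])

    def dipole(self, state: str, bond: int, reaction=None) -> float:
        sub = self._select(reaction)
        row = sub[(sub["state"] == state) & (sub["bond"] == bond)]
        if row.empty:
            raise SchemaError(f"missing dipole for ({state}, bond {bond})")
        return float(row["dipole_D"].iloc[0])

    def check_complete(self, reaction=None) -> None:
        """A complete table has both states × both bonds for every group."""
        sub = self._select(reaction)
        missing = []
        for group in sub["group"].unique():
            for state in _STATES:
                for bond in _BONDS:
                    sel = (
                        (sub["group"] == group)
                        & (sub["state"] == state)
                        & (sub["bond"] == bond)
                    )
                    if not sel.any():
                        missing.append((state, bond, group))
        if missing:
            raise SchemaError(f"incomplete snapshot table; missing keys {missing}")


def read_snapshot_table(path) -> SnapshotTable:
    return SnapshotTable.from_csv(path)


def load_reference_table() -> SnapshotTable:
    """Packaged reference snapshot table for the catalyzed/uncatalyzed
    reductive elimination (projected fields and bond dipoles by source group).
    """
    with resources.files("redelim.data").joinpath("reference_fields.csv").open() as fh:
        return SnapshotTable(pd.read_csv(fh, comment="#"))


# ---------------------------------------------------------------------------
# FES grids as three-column text with a metadata header

def write_fes(grid: FESGrid, path) -> None:
    with open(path, "w") as fh:
        fh.write("# redelim-fes 1\n")
        fh.write(f"# axis1 {grid.x[0]:.17g} {grid.x[-1]:.17g} {grid.x.size}\n")
        fh.write(f"# axis2 {grid.y[0]:.17g} {grid.y[-1]:.17g} {grid.y.size}\n")
        fh.write(f"# normalized {int(grid.normalized)}\n")
        fh.write(f"# metadata {json.dumps(grid.metadata, sort_keys=True)}\n")
        fh.write("# cv1 cv2 free_energy_kcal_mol\n")
        for i, xv in enumerate(grid.x):
            for j, yv in enumerate(grid.y):
                fh.write("%.17g %.17g %.17g\n" % (xv, yv, grid.values[i, j]))


def read_fes(path) -> FESGrid:
    header = {}
    with open(path) as fh:
        lines = fh.readlines()
    data = []
    for lineno, line in enumerate(lines, start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            parts = line[1:].split(None, 1)
            if parts and parts[0] in ("axis1", "axis2", "normalized", "metadata"):
                header[parts[0]] = parts[1]
            continue
        cols = line.split()
        if len(cols) != 3:
            raise SchemaError(f"line {lineno}: expected 3 columns")
        data.append([float(c) for c in cols])
    for key in ("axis1", "axis2"):
        if key not in header:
            raise SchemaError(f"FES file missing {key} header")
    x0, x1, nx = header["axis1"].split()
    y0, y1, ny = header["axis2"].split()
    nx, ny = int(nx), int(ny)
    arr = np.asarray(data)
    if arr.shape[0] != nx * ny:
        raise SchemaError(
            f"expected {nx * ny} rows for a {nx}x{ny} grid, got {arr.shape[0]}"
        )
    values = arr[:, 2].reshape(nx, ny)
    x = arr[:: ny, 0]
    y = arr[:ny, 1]
    return FESGrid(
        x=x,
        y=y,
        values=values,
        normalized=bool(int(header.get("normalized", "0"))),
        metadata=json.loads(header.get("metadata", "{}")),
    )
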