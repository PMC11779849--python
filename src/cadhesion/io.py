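"""File formats, core containers, configuration and logging.

Formats handled here:

* multi-MODEL PDB and XYZ for coordinate trajectories (``read_coordinates`` /
  ``write_coordinates``).  Only ``ATOM``/``HETATM``/``MODEL``/``ENDMDL``
  records are honoured; occupancy and B-factor are ignored on read and
  written as 1.00/0.00.
* tab-delimited tables for AFM force curves, generic observable traces and
  band-intensity tables.  Tables are UTF-8, header row mandatory, ``#``
  metadata lines before the header.
* binary aggregate masks as ASCII PGM (P2) or PNG.
* flat YAML run configuration.

Units follow the package convention (see :mod:`cadhesion.units`): trajectory
coordinates in Å and time in ps, AFM separation in nm and force in pN, FRAP
time in s.
"""

from __future__ import annotations

import dataclasses
import io as _stdio
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError, ParameterError, TopologyError

logger = logging.getLogger("cadhesion")


def setup_logging(level: str = "INFO", logfile: str | Path | None = None) -> logging.Logger:
    """Configure the package logger: stderr always, plus an optional file."""
    log = logging.getLogger("cadhesion")
    log.setLevel(getattr(logging, level.upper()))
    log.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    sh = logging.StreamHandler(sys.stderr)
    sh.setFormatter(fmt)
    log.addHandler(sh)
    if logfile is not None:
        fh = logging.FileHandler(logfile)
        fh.setFormatter(fmt)
        log.addHandler(fh)
    return log


# ---------------------------------------------------------------------------
# Core containers
# ---------------------------------------------------------------------------

@dataclass
class AtomRecord:
    """One atom of one frame: identity plus position in Å."""

    serial: int
    atom_name: str
    element: str
    residue_name: str
    residue_index: int
    chain_id: str
    position: np.ndarray

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ParameterError(f"position must be a 3-vector, got shape {self.position.shape}")
        if not np.all(np.isfinite(self.position)):
            raise ParameterError("position components must be finite")
        if self.serial <= 0:
            raise ParameterError("atom serial must be positive")
        if len(self.chain_id) != 1:
            raise ParameterError("chain_id must be a single character")


@dataclass
class CoordinateFrame:
    """An ordered snapshot of atoms at one timestamp (ps)."""

    atoms: list[AtomRecord]
    time: float = 0.0

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ParameterError("frame time must be >= 0")
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise TopologyError("atom serials must be unique within a frame")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(N, 3) coordinate array in Å; a copy, frame order preserved."""
        return np.array([a.position for a in self.atoms], dtype=float)

    def with_coords(self, coords: np.ndarray, time: float | None = None) -> "CoordinateFrame":
        """A new frame with identical topology but replaced coordinates."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise TopologyError("coordinate array shape does not match topology")
        atoms = [dataclasses.replace(a, position=coords[i]) for i, a in enumerate(self.atoms)]
        return CoordinateFrame(atoms=atoms, time=self.time if time is None else time)

    def select(self, predicate: Callable[[AtomRecord], bool]) -> np.ndarray:
        """Indices of atoms matching a predicate, in frame order."""
        return np.array([i for i, a in enumerate(self.atoms) if predicate(a)], dtype=int)


@dataclass
class Trajectory:
    """Topology-consistent ordered frames with a nominal sampling step (ps)."""

    frames: list[CoordinateFrame]
    dt: float = 1.0

    def __post_init__(self) -> None:
        if not self.frames:
            raise TopologyError("trajectory must contain at least one frame")
        n0 = self.frames[0].n_atoms
        for k, f in enumerate(self.frames):
            if f.n_atoms != n0:
                raise TopologyError(
                    f"frame {k} has {f.n_atoms} atoms, expected {n0} (inconsistent topology)"
                )
        times = np.array([f.time for f in self.frames])
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise TopologyError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_atoms(self) -> int:
        return self.frames[0].n_atoms

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    def coords(self) -> np.ndarray:
        """(n_frames, n_atoms, 3) stacked coordinates."""
        return np.stack([f.coords for f in self.frames])


@dataclass
class ForceCurve:
    """One AFM force-extension trace with instrument metadata."""

    curve_id: str
    separation: np.ndarray  # nm
    force: np.ndarray       # pN
    direction: str = "retract"
    velocity: float = 1.0           # µm/s
    spring_constant: float = 10.0   # pN/nm
    temperature: float = 298.15     # K

    def __post_init__(self) -> None:
        self.separation = np.asarray(self.separation, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.separation.shape != self.force.shape or self.separation.size < 2:
            raise ParameterError("separation and force must be equal-length arrays of length >= 2")
        if self.direction not in ("approach", "retract"):
            raise ParameterError(f"direction must be approach|retract, got {self.direction!r}")


@dataclass
class TimeSeries:
    """A generic labelled observable trace."""

    time: np.ndarray
    value: np.ndarray
    label: str = ""
    time_unit: str = "ps"
    value_unit: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.time.shape != self.value.shape:
            raise ParameterError("time and value must have equal length")
        if self.time.size > 1 and not np.all(np.diff(self.time) > 0):
            raise ParameterError("time must be strictly increasing")

    @property
    def dt(self) -> float:
        """Median sampling interval."""
        if self.time.size < 2:
            raise ParameterError("dt undefined for a single-sample series")
        return float(np.median(np.diff(self.time)))


@dataclass
class RunConfig:
    """Flat run configuration: seed plus the thresholds of every stage."""

    seed: int = 0
    out_dir: str = "results"
    temperature: float = 298.15          # K
    # force spectroscopy
    wlc_r2_min: float = 0.9
    lc_window: tuple[float, float] = (0.5, 1.5)   # × nominal tether length
    nominal_lc: float = 30.0             # nm, PEG tether contour length
    kmax: int = 4
    # trajectory metrics
    salt_bridge_cutoff: float = 4.0      # Å
    persistence_min: float = 0.40
    episode_min_ns: float = 0.2
    smooth_frames: int = 25
    dsasa_epsilon: float = 25.0          # Å²
    hold_frames: int = 5
    # FRAP
    r2_min: float = 0.7
    # quantification
    bead_min_px: int = 30
    single_cell_px: int = 40
    min_cells: int = 5

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise FormatError(f"config {path} must be a flat mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        if "lc_window" in raw:
            raw["lc_window"] = tuple(raw["lc_window"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["lc_window"] = list(d["lc_window"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


# ---------------------------------------------------------------------------
# Coordinates: PDB and XYZ
# ---------------------------------------------------------------------------

def _parse_pdb_atom(line: str, lineno: int) -> AtomRecord:
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        res_name = line[17:20].strip()
        chain = line[21]
        res_idx = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        element = line[76:78].strip() if len(line) >= 78 else ""
    except (ValueError, IndexError) as exc:
        raise FormatError(f"line {lineno}: unparseable ATOM/HETATM record: {exc}") from exc
    if chain == " ":
        raise FormatError(f"line {lineno}: chain identifier is required")
    if not element:
        element = "".join(c for c in name if c.isalpha())[:1].upper() or "X"
    return AtomRecord(serial=serial, atom_name=name, element=element,
                      residue_name=res_name, residue_index=res_idx,
                      chain_id=chain, position=np.array([x, y, z]))


def _read_pdb(path: Path, dt: float) -> Trajectory:
    frames: list[list[AtomRecord]] = []
    current: list[AtomRecord] | None = None
    seen_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "MODEL":
                seen_model = True
                if current:
                    frames.append(current)
                current = []
            elif rec == "ENDMDL":
                if current is not None:
                    frames.append(current)
                    current = None
            elif rec in ("ATOM", "HETATM"):
                if current is None:
                    if seen_model:
                        raise FormatError(f"line {lineno}: ATOM record outside MODEL block")
                    current = []
                current.append(_parse_pdb_atom(line.rstrip("\n"), lineno))
    if current:
        frames.append(current)
    if not frames:
        raise FormatError(f"{path}: no ATOM/HETATM records found")
    counts = {len(f) for f in frames}
    if len(counts) != 1:
        raise TopologyError(f"{path}: inconsistent atom counts across MODELs: {sorted(counts)}")
    return Trajectory(
        frames=[CoordinateFrame(atoms=f, time=i * dt) for i, f in enumerate(frames)],
        dt=dt,
    )


def _write_pdb(traj: Trajectory, path: Path) -> None:
    with open(path, "w") as fh:
        multi = traj.n_frames > 1
        for i, frame in enumerate(traj.frames):
            if multi:
                fh.write(f"MODEL     {i + 1:4d}\n")
            for a in frame.atoms:
                x, y, z = a.position
                fh.write(
                    f"ATOM  {a.serial:5d} {a.atom_name:<4s} {a.residue_name:>3s} "
                    f"{a.chain_id}{a.residue_index:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {a.element:>2s}\n"
                )
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


def _read_xyz(path: Path, dt: float) -> Trajectory:
    frames: list[list[AtomRecord]] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise FormatError(f"line {i + 1}: expected atom count, got {lines[i]!r}") from exc
        if i + 1 + n >= len(lines) + 1:
            raise FormatError(f"line {i + 1}: truncated frame (need {n} atoms)")
        atoms = []
        for j, row in enumerate(lines[i + 2:i + 2 + n]):
            parts = row.split()
            if len(parts) < 4:
                raise FormatError(f"line {i + 3 + j}: expected 'element x y z'")
            try:
                pos = np.array([float(parts[1]), float(parts[2]), float(parts[3])])
            except ValueError as exc:
                raise FormatError(f"line {i + 3 + j}: unparseable coordinate: {exc}") from exc
            atoms.append(AtomRecord(serial=j + 1, atom_name=parts[0], element=parts[0],
                                    residue_name="UNK", residue_index=j + 1,
                                    chain_id="A", position=pos))
        frames.append(atoms)
        i += 2 + n
    if not frames:
        raise FormatError(f"{path}: empty XYZ file")
    counts = {len(f) for f in frames}
    if len(counts) != 1:
        raise TopologyError(f"{path}: inconsistent atom counts across frames: {sorted(counts)}")
    return Trajectory(
        frames=[CoordinateFrame(atoms=f, time=i * dt) for i, f in enumerate(frames)],
        dt=dt,
    )


def _write_xyz(traj: Trajectory, path: Path) -> None:
    with open(path, "w") as fh:
        for frame in traj.frames:
            fh.write(f"{frame.n_atoms}\n")
            fh.write(f"t= {frame.time:.6g} ps\n")
            for a in frame.atoms:
                x, y, z = a.position
                fh.write(f"{a.element} {x:.6f} {y:.6f} {z:.6f}\n")


def read_coordinates(path: str | Path, dialect: str = "pdb", dt: float = 1.0) -> Trajectory:
    """Read a (possibly multi-frame) coordinate file into a :class:`Trajectory`.

    Frame times are assigned as ``i * dt`` (ps); single-frame files yield one
    frame at time 0.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "pdb":
        return _read_pdb(path, dt)
    if dialect == "xyz":
        return _read_xyz(path, dt)
    raise ParameterError(f"unknown coordinate dialect {dialect!r}")


def write_coordinates(traj: Trajectory, path: str | Path, dialect: str = "pdb") -> None:
    path = Path(path)
    if dialect == "pdb":
        _write_pdb(traj, path)
    elif dialect == "xyz":
        _write_xyz(traj, path)
    else:
        raise ParameterError(f"unknown coordinate dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Tabular formats
# ---------------------------------------------------------------------------

_CURVE_COLUMNS = ["curve_id", "separation_nm", "force_pN", "direction"]


def _read_tsv(path: Path) -> tuple[dict[str, str], pd.DataFrame]:
    """Read a TSV with '#'-prefixed key<TAB>value metadata lines before the header."""
    meta: dict[str, str] = {}
    body_lines: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                parts = line[1:].strip().split("\t", 1)
                if len(parts) == 2:
                    meta[parts[0].strip()] = parts[1].strip()
            else:
                body_lines.append(line)
    if not body_lines or not body_lines[0].strip():
        return meta, pd.DataFrame()
    df = pd.read_csv(_stdio.StringIO("".join(body_lines)), sep="\t", dtype=str)
    return meta, df


def _numeric_column(df: pd.DataFrame, col: str, path: Path) -> np.ndarray:
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = vals.isna() & df[col].notna()
    if bad.any():
        row = int(np.nonzero(bad.to_numpy())[0][0])
        raise FormatError(f"{path}: non-numeric value {df[col].iloc[row]!r} "
                          f"in column {col!r} at data row {row}")
    return vals.to_numpy(dtype=float)


def read_force_curves(path: str | Path) -> list[ForceCurve]:
    """Read AFM curves from a TSV; one :class:`ForceCurve` per (curve_id, direction)."""
    path = Path(path)
    meta, df = _read_tsv(path)
    if df.empty:
        logger.warning("%s: empty force-curve table", path)
        return []
    missing = [c for c in _CURVE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    sep = _numeric_column(df, "separation_nm", path)
    force = _numeric_column(df, "force_pN", path)
    velocity = float(meta.get("velocity_um_s", 1.0))
    k = float(meta.get("spring_constant_pN_nm", 10.0))
    temp = float(meta.get("temperature_K", 298.15))
    curves = []
    keys = df[["curve_id", "direction"]].apply(tuple, axis=1)
    for key in keys.drop_duplicates():
        idx = (keys == key).to_numpy()
        curves.append(ForceCurve(
            curve_id=str(key[0]), separation=sep[idx], force=force[idx],
            direction=str(key[1]), velocity=velocity, spring_constant=k,
            temperature=temp,
        ))
    return curves


def write_force_curves(curves: Sequence[ForceCurve], path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        if curves:
            fh.write(f"# velocity_um_s\t{curves[0].velocity:.8g}\n")
            fh.write(f"# spring_constant_pN_nm\t{curves[0].spring_constant:.8g}\n")
            fh.write(f"# temperature_K\t{curves[0].temperature:.8g}\n")
        fh.write("\t".join(_CURVE_COLUMNS) + "\n")
        for c in curves:
            for s, f in zip(c.separation, c.force):
                fh.write(f"{c.curve_id}\t{s:.8g}\t{f:.8g}\t{c.direction}\n")


def read_timeseries(path: str | Path) -> TimeSeries:
    """Read one observable trace from a two-column TSV (time, value)."""
    path = Path(path)
    meta, df = _read_tsv(path)
    if df.empty or "time" not in df.columns or "value" not in df.columns:
        raise FormatError(f"{path}: trace TSV requires 'time' and 'value' columns")
    return TimeSeries(
        time=_numeric_column(df, "time", path),
        value=_numeric_column(df, "value", path),
        label=meta.get("label", path.stem),
        time_unit=meta.get("time_unit", "ps"),
        value_unit=meta.get("value_unit", ""),
    )


def write_timeseries(ts: TimeSeries, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# label\t{ts.label}\n")
        fh.write(f"# time_unit\t{ts.time_unit}\n")
        fh.write(f"# value_unit\t{ts.value_unit}\n")
        fh.write("time\tvalue\n")
        for t, v in zip(ts.time, ts.value):
            fh.write(f"{t:.8g}\t{v:.8g}\n")


_BAND_COLUMNS = ["condition", "band", "intensity", "replicate"]


def read_band_table(path: str | Path) -> pd.DataFrame:
    """Read a band-intensity table (condition, band, intensity, replicate)."""
    path = Path(path)
    _, df = _read_tsv(path)
    missing = [c for c in _BAND_COLUMNS if c not in df.columns]
    if df.empty or missing:
        raise FormatError(f"{path}: band table requires columns {_BAND_COLUMNS}")
    out = df[_BAND_COLUMNS].copy()
    out["intensity"] = _numeric_column(df, "intensity", path)
    if (out["intensity"] < 0).any():
        raise FormatError(f"{path}: band intensities must be >= 0")
    dup = out.duplicated(subset=["condition", "band", "replicate"])
    if dup.any():
        raise FormatError(f"{path}: duplicate (condition, band, replicate) rows")
    return out


def write_band_table(df: pd.DataFrame, path: str | Path) -> None:
    df[_BAND_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.8g")


# ---------------------------------------------------------------------------
# Binary masks
# ---------------------------------------------------------------------------

def read_mask(path: str | Path) -> np.ndarray:
    """Read a binary aggregate mask from PGM (P2 ASCII) or PNG."""
    path = Path(path)
    if path.suffix.lower() == ".pgm":
        tokens = []
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0]
                tokens.extend(line.split())
        if not tokens or tokens[0] != "P2":
            raise FormatError(f"{path}: expected ASCII PGM (P2) header")
        w, h, maxval = int(tokens[1]), int(tokens[2]), int(tokens[3])
        data = np.array(tokens[4:4 + w * h], dtype=int).reshape(h, w)
        arr = data
    else:
        import imageio.v3 as iio
        arr = np.asarray(iio.imread(path))
        if arr.ndim == 3:
            arr = arr[..., 0]
    mask = arr > 0
    return mask


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    path = Path(path)
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise FormatError("mask must be a 2-D array")
    if path.suffix.lower() == ".pgm":
        h, w = mask.shape
        with open(path, "w") as fh:
            fh.write(f"P2\n{w} {h}\n1\n")
            for row in mask.astype(int):
                fh.write(" ".join(str(v) for v in row) + "\n")
    else:
        import imageio.v3 as iio
        iio.imwrite(path, (mask.astype(np.uint8) * 255))


# ---------------------------------------------------------------------------
# JSON summaries
# ---------------------------------------------------------------------------

def write_json(obj: dict, path: str | Path) -> None:
    """Deterministic JSON output (sorted keys, fixed float repr)."""

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, sort_keys=True, indent=1, default=_default) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
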