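"""Trajectory-derived structural observables.

Superposition and RMSD/RMSF, solvent-accessible surface area (SASA) and the
interfacial burial ΔSASA = SASA(A) + SASA(B) − SASA(AB), charged-atom
distances and salt-bridge stability calls, interaction occupancy/episode
statistics, and the event-time estimators used to time the X-dimer →
S-dimer conversion (RMSD minimum) and dimer dissociation (ΔSASA reaching
zero) in steered-MD observable traces.

All coordinates are in Å, times in ps unless a series says otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.spatial import cKDTree

from .errors import AnalysisError, GeometryError, ParameterError, TopologyError
from .io import AtomRecord, CoordinateFrame, TimeSeries, Trajectory
from .units import kj_mol_nm_to_pn as _kj_mol_nm_to_pn

AtomPredicate = Callable[[AtomRecord], bool]

#: van der Waals radii (Å) used for SASA, by element symbol.
VDW_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52,
    "S": 1.80, "P": 1.80, "SE": 1.90, "F": 1.47, "CL": 1.75,
}


# ---------------------------------------------------------------------------
# Selections
# ---------------------------------------------------------------------------

def select_all(_: AtomRecord) -> bool:
    return True


def alpha_carbons(a: AtomRecord) -> bool:
    return a.atom_name == "CA"


def chain(chain_id: str) -> AtomPredicate:
    return lambda a: a.chain_id == chain_id


def lysine_nz(a: AtomRecord) -> bool:
    """Charged donor atom of a lysine side chain."""
    return a.residue_name == "LYS" and a.atom_name == "NZ"


def acidic_oxygens(a: AtomRecord) -> bool:
    """Charged acceptor oxygens of Asp/Glu side chains."""
    return (a.residue_name == "ASP" and a.atom_name in ("OD1", "OD2")) or \
           (a.residue_name == "GLU" and a.atom_name in ("OE1", "OE2"))


def _subframe(frame: CoordinateFrame, idx: np.ndarray) -> CoordinateFrame:
    return CoordinateFrame(atoms=[frame.atoms[i] for i in idx], time=frame.time)


# ---------------------------------------------------------------------------
# Superposition, RMSD, RMSF
# ---------------------------------------------------------------------------

@dataclass
class Superposition:
    rotation: np.ndarray     # 3×3, proper (det +1)
    translation: np.ndarray  # Å
    rmsd: float              # Å, over the selection used for the fit

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def _kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal proper rotation R and translation t with R·P + t ≈ Q."""
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    return R, t


def kabsch_superpose(mobile: CoordinateFrame, reference: CoordinateFrame,
                     selection: AtomPredicate = select_all) -> Superposition:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Atoms are matched 1:1 by order within the selection; reflections are
    excluded by the determinant correction.
    """
    im = mobile.select(selection)
    ir = reference.select(selection)
    if im.size != ir.size:
        raise TopologyError(
            f"selection sizes differ: {im.size} (mobile) vs {ir.size} (reference)")
    if im.size < 3:
        raise GeometryError("need at least 3 selected atoms to superpose")
    P = mobile.coords[im]
    Q = reference.coords[ir]
    sv = np.linalg.svd(P - P.mean(axis=0), compute_uv=False)
    if sv[1] < 1e-8:
        raise GeometryError("selected atoms are collinear; superposition is degenerate")
    R, t = _kabsch(P, Q)
    moved = P @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1))))
    return Superposition(rotation=R, translation=t, rmsd=rmsd)


def rmsd_trace(traj: Trajectory, reference: CoordinateFrame,
               selection: AtomPredicate = select_all,
               superpose: bool = True) -> TimeSeries:
    """Per-frame RMSD to a reference, after per-frame optimal superposition
    (set ``superpose=False`` to compare in the laboratory frame)."""
    ir = reference.select(selection)
    values = []
    for frame in traj.frames:
        im = frame.select(selection)
        if im.size != ir.size:
            raise TopologyError("selection does not match between trajectory and reference")
        if superpose:
            values.append(kabsch_superpose(frame, reference, selection).rmsd)
        else:
            d = frame.coords[im] - reference.coords[ir]
            values.append(float(np.sqrt(np.mean(np.sum(d ** 2, axis=1)))))
    return TimeSeries(time=traj.times, value=np.array(values),
                      label="rmsd", time_unit="ps", value_unit="A")


@dataclass
class RMSFProfile:
    values: dict[int, float]        # residue_index -> RMSF, Å
    window: tuple[float, float]     # ps


def rmsf_profile(traj: Trajectory, selection: AtomPredicate = alpha_carbons,
                 window: tuple[float, float] | None = None) -> RMSFProfile:
    """Per-residue root-mean-square fluctuation about the mean structure.

    Frames inside the window are first superposed onto the first window frame,
    the mean structure is computed, and all frames are re-superposed onto that
    mean (two-pass) before the fluctuations are measured.  With one selected
    atom per residue (the default α-carbon selection) the profile is per-atom.
    """
    times = traj.times
    if window is None:
        window = (float(times[0]), float(times[-1]))
    in_win = (times >= window[0]) & (times <= window[1])
    frames = [f for f, ok in zip(traj.frames, in_win) if ok]
    if not frames:
        raise AnalysisError("empty RMSF window")
    if len(frames) < 10:
        raise AnalysisError(f"need >= 10 frames in the RMSF window, got {len(frames)}")
    idx = frames[0].select(selection)
    if idx.size < 3:
        raise GeometryError("RMSF selection must contain at least 3 atoms")
    coords = np.stack([f.coords[f.select(selection)] for f in frames])

    def _fit_all(target: np.ndarray) -> np.ndarray:
        out = np.empty_like(coords)
        for k in range(coords.shape[0]):
            P = coords[k]
            R, t = _kabsch(P, target)
            out[k] = P @ R.T + t
        return out

    pass1 = _fit_all(coords[0])
    mean1 = pass1.mean(axis=0)
    pass2 = _fit_all(mean1)
    mean2 = pass2.mean(axis=0)
    rmsf = np.sqrt(np.mean(np.sum((pass2 - mean2) ** 2, axis=2), axis=0))
    residues = [frames[0].atoms[i].residue_index for i in idx]
    values: dict[int, list[float]] = {}
    for r, v in zip(residues, rmsf):
        values.setdefault(r, []).append(float(v))
    return RMSFProfile(
        values={r: float(np.mean(v)) for r, v in values.items()},
        window=window,
    )


# ---------------------------------------------------------------------------
# SASA and ΔSASA
# ---------------------------------------------------------------------------

@dataclass
class SASAResult:
    per_atom: np.ndarray  # Å²
    total: float          # Å²
    probe_radius: float   # Å
    n_sphere_points: int


def _spiral_points(n: int) -> np.ndarray:
    """Deterministic generalized-spiral (golden-angle) lattice on the unit sphere."""
    k = np.arange(n) + 0.5
    z = 1.0 - 2.0 * k / n
    theta = np.arccos(np.clip(z, -1, 1))
    phi = k * np.pi * (3.0 - np.sqrt(5.0))
    st = np.sin(theta)
    return np.column_stack([st * np.cos(phi), st * np.sin(phi), z])


def shrake_rupley_sasa(frame: CoordinateFrame,
                       radii: dict[str, float] | None = None,
                       probe: float = 1.4,
                       n_points: int = 960) -> SASAResult:
    """Shrake–Rupley accessible surface area with a deterministic lattice.

    Each atom is inflated by the probe radius, covered with ``n_points`` test
    points, and a point counts as accessible when no neighbouring inflated
    sphere contains it.
    """
    if probe < 0:
        raise ParameterError("probe radius must be >= 0")
    if n_points < 92:
        raise ParameterError("n_points must be >= 92 for a usable lattice")
    table = VDW_RADII if radii is None else radii
    try:
        r = np.array([table[a.element.upper()] for a in frame.atoms])
    except KeyError as exc:
        raise ParameterError(f"no van der Waals radius for element {exc.args[0]!r}") from exc
    pos = frame.coords
    n = len(frame.atoms)
    inflated = r + probe
    lattice = _spiral_points(n_points)
    tree = cKDTree(pos)
    max_reach = 2.0 * inflated.max()
    per_atom = np.empty(n)
    for i in range(n):
        pts = pos[i] + inflated[i] * lattice
        neighbors = [j for j in tree.query_ball_point(pos[i], max_reach) if j != i]
        if neighbors:
            nb_pos = pos[neighbors]
            nb_r = inflated[neighbors]
            d2 = np.sum((pts[:, None, :] - nb_pos[None, :, :]) ** 2, axis=2)
            buried = np.any(d2 < (nb_r ** 2)[None, :] - 1e-12, axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        per_atom[i] = 4.0 * np.pi * inflated[i] ** 2 * frac
    return SASAResult(per_atom=per_atom, total=float(per_atom.sum()),
                      probe_radius=probe, n_sphere_points=n_points)


def delta_sasa(frame: CoordinateFrame, chain_a: AtomPredicate, chain_b: AtomPredicate,
               radii: dict[str, float] | None = None,
               probe: float = 1.4, n_points: int = 960) -> float:
    """Interfacial burial ΔSASA = SASA(A) + SASA(B) − SASA(A∪B), Å².

    Non-negative up to lattice noise; small negative values are clamped to 0.
    """
    ia = frame.select(chain_a)
    ib = frame.select(chain_b)
    if ia.size == 0 or ib.size == 0:
        raise GeometryError("both chain selections must be non-empty")
    if np.intersect1d(ia, ib).size:
        raise GeometryError("chain selections overlap")
    kw = dict(radii=radii, probe=probe, n_points=n_points)
    sasa_a = shrake_rupley_sasa(_subframe(frame, ia), **kw).total
    sasa_b = shrake_rupley_sasa(_subframe(frame, ib), **kw).total
    sasa_ab = shrake_rupley_sasa(_subframe(frame, np.concatenate([ia, ib])), **kw).total
    return max(sasa_a + sasa_b - sasa_ab, 0.0)


def delta_sasa_trace(traj: Trajectory, chain_a: AtomPredicate, chain_b: AtomPredicate,
                     **kwargs) -> TimeSeries:
    values = [delta_sasa(f, chain_a, chain_b, **kwargs) for f in traj.frames]
    return TimeSeries(time=traj.times, value=np.array(values),
                      label="dsasa", time_unit="ps", value_unit="A^2")


# ---------------------------------------------------------------------------
# Salt bridges and interaction statistics
# ---------------------------------------------------------------------------

@dataclass
class SaltBridgeCall:
    pair_label: str
    median_distance: float        # Å
    window: tuple[float, float]   # trace time units
    stable: bool                  # median strictly below the cutoff
    cutoff: float                 # Å


def charged_pair_distances(traj: Trajectory,
                           donor: AtomPredicate = lysine_nz,
                           acceptor: AtomPredicate = acidic_oxygens,
                           label: str = "") -> TimeSeries:
    """Per-frame minimum distance between any donor and any acceptor charged
    atom (Å).  Defaults: Lys NZ vs Asp/Glu carboxylate oxygens."""
    id_ = traj.frames[0].select(donor)
    ia = traj.frames[0].select(acceptor)
    if id_.size == 0 or ia.size == 0:
        raise GeometryError("donor and acceptor selections must be non-empty")
    values = []
    for frame in traj.frames:
        c = frame.coords
        d = np.linalg.norm(c[id_][:, None, :] - c[ia][None, :, :], axis=2)
        values.append(float(d.min()))
    return TimeSeries(time=traj.times, value=np.array(values),
                      label=label or "charged_pair_distance",
                      time_unit="ps", value_unit="A")


def salt_bridge_call(trace: TimeSeries,
                     window: tuple[float, float] | None = None,
                     cutoff: float = 4.0) -> SaltBridgeCall:
    """Median-distance stability call: stable iff the median charged-atom
    distance over the window is strictly below the cutoff (default 4 Å).

    The default window is the last two thirds of the trace (the equilibrated
    portion, mirroring the convention of analysing the tail of an MD run).
    """
    t, v = trace.time, trace.value
    if window is None:
        window = (float(t[0] + (t[-1] - t[0]) / 3.0), float(t[-1]))
    sel = (t >= window[0]) & (t <= window[1])
    if not np.any(sel):
        raise AnalysisError("salt-bridge window contains no samples")
    med = float(np.median(v[sel]))
    return SaltBridgeCall(pair_label=trace.label, median_distance=med,
                          window=window, stable=bool(med < cutoff), cutoff=cutoff)


def interaction_occupancy(contact: TimeSeries | np.ndarray,
                          persistence_min: float = 0.40) -> tuple[float, bool]:
    """Fraction of frames in contact, and whether the interaction is
    persistent (occupancy >= persistence_min, boundary inclusive)."""
    values = contact.value if isinstance(contact, TimeSeries) else np.asarray(contact)
    if values.size == 0:
        raise AnalysisError("empty contact series")
    occ = float(np.mean(values.astype(bool)))
    return occ, bool(occ >= persistence_min)


def interaction_episodes(contact: TimeSeries,
                         min_duration_ns: float = 0.2) -> list[tuple[float, float]]:
    """Maximal contact runs as (start, end) time spans, keeping only spans
    strictly longer than ``min_duration_ns``.

    The trace time unit is ps; a run of m frames at sampling step dt spans
    m·dt ps, i.e. each frame represents one sampling interval of contact.
    """
    b = contact.value.astype(bool)
    dt = contact.dt
    episodes = []
    i = 0
    n = b.size
    while i < n:
        if b[i]:
            j = i
            while j + 1 < n and b[j + 1]:
                j += 1
            duration_ns = (j - i + 1) * dt / 1000.0
            if duration_ns > min_duration_ns:
                episodes.append((float(contact.time[i]),
                                 float(contact.time[i] + (j - i + 1) * dt)))
            i = j + 1
        else:
            i += 1
    return episodes


# ---------------------------------------------------------------------------
# Event-time estimators
# ---------------------------------------------------------------------------

@dataclass
class EventTime:
    kind: str                  # "conversion" | "dissociation"
    time: float | None         # trace time units; None when no event found
    window: int                # smoothing frames (conversion) / hold frames (dissociation)
    threshold: float           # noise SD used (conversion) / epsilon (dissociation)


def conversion_time(rmsd: TimeSeries, smooth_frames: int = 25) -> EventTime:
    """Time of the drop-then-rise minimum of an RMSD trace.

    The trace is smoothed by a centred moving average and the global minimum
    is reported, provided it is interior: some earlier and some later smoothed
    value must exceed the minimum by at least one noise SD (estimated from
    first differences of the raw trace).  A monotone trace yields no event.
    """
    y = rmsd.value
    t = rmsd.time
    n = y.size
    w = max(1, int(smooth_frames))
    if n < 2 * w:
        raise AnalysisError("trace shorter than twice the smoothing window")
    ys = np.convolve(y, np.ones(w) / w, mode="valid")
    ts = t[w // 2: n - (w - 1 - w // 2)]
    sigma = float(np.std(np.diff(y)) / np.sqrt(2.0))
    i = int(np.argmin(ys))
    interior = (np.any(ys[:i] > ys[i] + sigma) and
                np.any(ys[i + 1:] > ys[i] + sigma))
    return EventTime(kind="conversion",
                     time=float(ts[i]) if interior else None,
                     window=w, threshold=sigma)


def dissociation_time(dsasa: TimeSeries, epsilon: float = 25.0,
                      hold_frames: int = 5) -> EventTime:
    """First time a ΔSASA trace falls to (and stays at) zero.

    Reports the first sample whose value is <= epsilon with the following
    ``hold_frames − 1`` samples also <= epsilon; isolated noise dips shorter
    than the hold are ignored.  None when the trace never stays down.
    """
    if epsilon < 0:
        raise ParameterError("epsilon must be >= 0")
    below = dsasa.value <= epsilon
    h = max(1, int(hold_frames))
    n = below.size
    for i in range(0, n - h + 1):
        if below[i:i + h].all():
            return EventTime(kind="dissociation", time=float(dsasa.time[i]),
                             window=h, threshold=epsilon)
    return EventTime(kind="dissociation", time=None, window=h, threshold=epsilon)


def convert_force_units(f: float) -> float:
    """Convert a pulling force in kJ·mol⁻¹·nm⁻¹ to pN (≈1.6605 pN each)."""
    if not np.isfinite(f):
        raise ParameterError("force must be finite")
    return _kj_mol_nm_to_pn(f)
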