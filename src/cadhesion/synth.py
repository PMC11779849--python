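"""Synthetic inputs with planted ground truth for every pipeline stage.

Every generator is a pure function of its parameters and a seed, and each
dataset comes with a :class:`GroundTruthLedger` entry recording the planted
quantities (rupture forces and curve classes, WLC tether parameters, FRAP
kinetics, event times, occupancies, blob sizes) so that downstream
estimators can be tested for parameter recovery.

The AFM generator and the fitter deliberately share one WLC model
(Marko–Siggia): the purpose of the synthetic data is parameter recovery,
not model discrimination.  Rupture is modelled as force truncation of the
tether curve at a force drawn from the planted Gaussian mixture; noise is
additive Gaussian everywhere.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ParameterError, PlacementError
from .force import wlc_extension_at_force, wlc_force
from .frap import RecoveryTrace, recovery_model
from .io import AtomRecord, CoordinateFrame, ForceCurve, TimeSeries, Trajectory

#: Rupture forces are resampled below this floor (pN): forces of a few pN sit
#: at the thermal detection limit of the instrument and would never be scored.
MIN_RUPTURE_PN = 5.0


@dataclass
class GroundTruthLedger:
    """Per-dataset map of planted parameters."""

    datasets: dict[str, dict] = field(default_factory=dict)

    def add(self, name: str, **params) -> None:
        if name in self.datasets:
            raise ParameterError(f"duplicate ledger entry {name!r}")
        self.datasets[name] = params

    def __getitem__(self, name: str) -> dict:
        return self.datasets[name]

    def to_json(self, path: str | Path) -> None:
        def _default(o):
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            raise TypeError(type(o))
        Path(path).write_text(
            json.dumps(self.datasets, sort_keys=True, indent=1, default=_default) + "\n")


@dataclass
class MixtureSpec:
    """A 1-D Gaussian mixture of rupture forces: (weight, mean pN, sd pN)."""

    components: list[tuple[float, float, float]]

    def __post_init__(self) -> None:
        w = sum(c[0] for c in self.components)
        if abs(w - 1.0) > 1e-9:
            raise ParameterError(f"mixture weights sum to {w}, expected 1")
        for wi, mu, sd in self.components:
            if wi <= 0 or mu <= 0 or sd <= 0:
                raise ParameterError("weights and means must be > 0, sds > 0")

    def sample(self, n: int, rng: np.random.Generator,
               floor: float = MIN_RUPTURE_PN) -> np.ndarray:
        """Draw n forces, resampling any draw below the detection floor."""
        weights = np.array([c[0] for c in self.components])
        means = np.array([c[1] for c in self.components])
        sds = np.array([c[2] for c in self.components])
        out = np.empty(n)
        for i in range(n):
            f = -np.inf
            while f < floor:
                j = rng.choice(len(weights), p=weights)
                f = rng.normal(means[j], sds[j])
            out[i] = f
        return out


# ---------------------------------------------------------------------------
# AFM force curves
# ---------------------------------------------------------------------------

def gen_afm_curves(spec: MixtureSpec, n_curves: int,
                   tether: tuple[float, float] = (0.38, 30.0),
                   specific_fraction: float = 0.7,
                   noise_sd: float = 1.0,
                   temperature: float = 298.15,
                   seed: int = 0,
                   n_points: int = 500) -> tuple[list[ForceCurve], GroundTruthLedger]:
    """Synthetic constant-velocity retract curves.

    Specific curves follow the Marko–Siggia tether stretch truncated at a
    rupture force drawn from ``spec``, then drop instantaneously to baseline.
    Nonspecific curves carry adhesion signatures that fail the WLC filter:
    jagged multi-peak sawtooths or immediate detachment spikes.
    """
    p, lc = tether
    if p <= 0 or lc <= 0:
        raise ParameterError("tether persistence and contour length must be > 0")
    if n_curves < 1:
        raise ParameterError("n_curves must be >= 1")
    if not 0 <= specific_fraction <= 1:
        raise ParameterError("specific_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    curves: list[ForceCurve] = []
    ledger = GroundTruthLedger()
    per_curve: dict[str, dict] = {}

    n_pre = int(0.7 * n_points)
    n_post = n_points - n_pre
    for i in range(n_curves):
        cid = f"c{i:05d}"
        is_specific = rng.random() < specific_fraction
        if is_specific:
            f_rupt = float(spec.sample(1, rng)[0])
            x_r = wlc_extension_at_force(f_rupt, p, lc, temperature)
            x_pre = np.linspace(0.0, x_r, n_pre)
            x_post = x_r + (0.4 * x_r) * np.linspace(1, n_post, n_post) / n_post
            x = np.concatenate([x_pre, x_post])
            f = np.concatenate([wlc_force(x_pre, p, lc, temperature),
                                np.zeros(n_post)])
            f[n_pre - 1] = f_rupt  # the sample at the drop carries the planted force
            per_curve[cid] = {"class": "specific", "rupture_force_pN": f_rupt,
                              "rupture_extension_nm": x_r}
        else:
            x = np.linspace(0.0, 0.9 * lc * rng.uniform(0.6, 1.0), n_points)
            f = np.zeros(n_points)
            if rng.random() < 0.5:
                # jagged multi-peak adhesion sawtooth
                n_seg = int(rng.integers(2, 5))
                bounds = np.sort(rng.uniform(0.05, 0.75, n_seg))
                start = 0.0
                for b in np.append(bounds, 0.8):
                    seg = (x >= start * x[-1]) & (x < b * x[-1])
                    if seg.sum() > 2:
                        peak = rng.uniform(20.0, 80.0)
                        f[seg] = np.linspace(0, peak, seg.sum())
                    start = b
                per_curve[cid] = {"class": "nonspecific", "shape": "sawtooth"}
            else:
                # immediate detachment: adhesion spike at near-zero separation
                spike = x < 1.5
                f[spike] = rng.uniform(50.0, 150.0) * np.exp(-x[spike] / 0.3)
                per_curve[cid] = {"class": "nonspecific", "shape": "detach"}
        if noise_sd > 0:
            f = f + rng.normal(0.0, noise_sd, f.size)
        curves.append(ForceCurve(curve_id=cid, separation=x, force=f,
                                 direction="retract", temperature=temperature))
    ledger.add("afm", mixture=[list(c) for c in spec.components],
               tether_p_nm=p, tether_lc_nm=lc, noise_sd_pN=noise_sd,
               specific_fraction=specific_fraction, curves=per_curve)
    return curves, ledger


# ---------------------------------------------------------------------------
# FRAP traces
# ---------------------------------------------------------------------------

def gen_frap_traces(A: float, k: float, t0: float | None = None,
                    n_pre: int = 10, n_post: int = 200,
                    frame_interval: float = 0.863,
                    noise_sd: float = 0.03, seed: int = 0,
                    n_traces: int = 1,
                    intensity_scale: float = 1000.0,
                    background: float = 100.0
                    ) -> tuple[list[RecoveryTrace], GroundTruthLedger]:
    """Raw FRAP intensity traces: pre-bleach plateau at 1 (in normalized
    units), bleach drop, then A(1 − e^{−k(t−t0)}) recovery plus Gaussian
    noise, mapped to arbitrary units with a background offset.

    Defaults mirror a confocal protocol of 10 pre-bleach and 200 post-bleach
    frames at 0.863 s per frame.
    """
    if not 0 < A <= 1:
        raise ParameterError("mobile fraction A must lie in (0, 1]")
    if k <= 0:
        raise ParameterError("recovery rate k must be > 0")
    if n_post < 10:
        raise ParameterError("need >= 10 post-bleach frames for a determined fit")
    if n_pre < 3:
        raise ParameterError("need >= 3 pre-bleach frames")
    dt = frame_interval
    if t0 is None:
        t0 = n_pre * dt
    rng = np.random.default_rng(seed)
    t_pre = np.arange(n_pre) * dt
    t_post = t0 + np.arange(n_post) * dt
    t = np.concatenate([t_pre, t_post])
    y_true = np.concatenate([np.ones(n_pre), recovery_model(t_post, A, k, t0)])
    traces = []
    ledger = GroundTruthLedger()
    for j in range(n_traces):
        y = y_true if noise_sd == 0 else y_true + rng.normal(0, noise_sd, t.size)
        traces.append(RecoveryTrace(
            time=t, intensity=background + intensity_scale * y,
            background=background, bleach_index=n_pre, trace_id=f"frap{j:03d}"))
    ledger.add("frap", A=A, k_per_s=k, t0_s=float(t0),
               t_half_s=float(np.log(2) / k), noise_sd=noise_sd,
               n_traces=n_traces)
    return traces, ledger


# ---------------------------------------------------------------------------
# Observable traces (RMSD / ΔSASA / distances)
# ---------------------------------------------------------------------------

def gen_event_trace(kind: str, event_time: float, dt: float, horizon: float,
                    noise_sd: float, seed: int = 0,
                    rmsd_min: float = 1.0, rmsd_slope: float = 0.005,
                    dsasa_initial: float = 800.0,
                    dsasa_fall_ps: float = 100.0) -> TimeSeries:
    """A steered-MD-like observable trace with a planted event time (ps).

    ``rmsd`` kind: symmetric piecewise-linear V with its minimum at the
    event time (the X→S conversion signature: the RMSD to the reference
    first drops, then rises again as the dimer is pulled apart).

    ``dsasa`` kind: plateau at ``dsasa_initial``, then an abrupt linear fall
    over ``dsasa_fall_ps`` reaching 0 exactly at the event time and clamped
    at 0 after (dimer dissociation; interface loss on rupture is fast
    compared with the preceding pulling phase).
    """
    if not 0 < event_time < horizon:
        raise ParameterError("event_time must lie strictly inside (0, horizon)")
    if dt <= 0 or dt >= horizon:
        raise ParameterError("dt must satisfy 0 < dt < horizon")
    rng = np.random.default_rng(seed)
    t = np.arange(int(np.floor(horizon / dt)) + 1) * dt
    if kind == "rmsd":
        v = rmsd_min + rmsd_slope * np.abs(t - event_time)
        unit = "A"
    elif kind == "dsasa":
        t_knee = event_time - min(dsasa_fall_ps, event_time / 2.0)
        v = np.where(t <= t_knee, dsasa_initial,
                     dsasa_initial * (event_time - t) / (event_time - t_knee))
        v = np.clip(v, 0.0, None)
        unit = "A^2"
    else:
        raise ParameterError(f"kind must be rmsd|dsasa, got {kind!r}")
    if noise_sd > 0:
        v = v + rng.normal(0, noise_sd, v.size)
    return TimeSeries(time=t, value=v, label=kind, time_unit="ps", value_unit=unit)


def gen_distance_trace(occupancy: float, bound_mean: float, unbound_mean: float,
                       n_frames: int, seed: int = 0,
                       bound_sd: float = 0.3, unbound_sd: float = 0.3,
                       mean_dwell_frames: float = 10.0) -> TimeSeries:
    """Two-state telegraph charged-atom distance series (Å).

    State dwell times are geometric; switching rates are chosen so the
    stationary bound fraction equals ``occupancy``.
    """
    if not bound_mean < unbound_mean:
        raise ParameterError("bound_mean must be below unbound_mean")
    if not 0 <= occupancy <= 1:
        raise ParameterError("occupancy must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    if occupancy in (0.0, 1.0):
        bound = np.full(n_frames, occupancy == 1.0, dtype=bool)
    else:
        q_bu = min(1.0, 1.0 / mean_dwell_frames)              # leave bound
        q_ub = min(1.0, q_bu * occupancy / (1.0 - occupancy))  # leave unbound
        bound = np.empty(n_frames, dtype=bool)
        state = rng.random() < occupancy
        for i in range(n_frames):
            bound[i] = state
            if state and rng.random() < q_bu:
                state = False
            elif not state and rng.random() < q_ub:
                state = True
    value = np.where(bound,
                     rng.normal(bound_mean, bound_sd, n_frames),
                     rng.normal(unbound_mean, unbound_sd, n_frames))
    return TimeSeries(time=np.arange(n_frames, dtype=float), value=value,
                      label="distance", time_unit="ps", value_unit="A")


# ---------------------------------------------------------------------------
# Toy dimer trajectory
# ---------------------------------------------------------------------------

def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def gen_toy_dimer(n_atoms_per_chain: int, separation: float,
                  jitter_sd: float, n_frames: int, seed: int = 0,
                  dt: float = 1.0, chain_radius: float = 4.0
                  ) -> tuple[Trajectory, GroundTruthLedger]:
    """A two-chain pseudo-atom dimer trajectory: per-frame rigid-body motion
    of the whole complex plus isotropic Gaussian jitter per atom.

    Chains A and B are random carbon blobs of radius ``chain_radius`` Å with
    centres ``separation`` Å apart; every pseudo-atom is named CA so the
    default α-carbon selections resolve.
    """
    if n_atoms_per_chain < 4:
        raise ParameterError("need at least 4 atoms per chain")
    rng = np.random.default_rng(seed)

    def _blob(center):
        pts = []
        while len(pts) < n_atoms_per_chain:
            p = rng.uniform(-chain_radius, chain_radius, 3)
            if np.linalg.norm(p) <= chain_radius:
                pts.append(p + center)
        return np.array(pts)

    base = np.vstack([_blob(np.zeros(3)),
                      _blob(np.array([separation, 0.0, 0.0]))])
    n_total = 2 * n_atoms_per_chain
    frames = []
    for fidx in range(n_frames):
        R = _random_rotation(rng)
        trans = rng.normal(0, 5.0, 3)
        coords = base @ R.T + trans
        if jitter_sd > 0:
            coords = coords + rng.normal(0, jitter_sd, coords.shape)
        atoms = []
        for i in range(n_total):
            chain_id = "A" if i < n_atoms_per_chain else "B"
            atoms.append(AtomRecord(
                serial=i + 1, atom_name="CA", element="C", residue_name="GLY",
                residue_index=(i % n_atoms_per_chain) + 1, chain_id=chain_id,
                position=coords[i]))
        frames.append(CoordinateFrame(atoms=atoms, time=fidx * dt))
    ledger = GroundTruthLedger()
    ledger.add("dimer", jitter_sd_A=jitter_sd, separation_A=separation,
               n_atoms_per_chain=n_atoms_per_chain, chain_radius_A=chain_radius)
    return Trajectory(frames=frames, dt=dt), ledger


# ---------------------------------------------------------------------------
# Aggregate masks
# ---------------------------------------------------------------------------

def gen_aggregate_mask(blob_sizes: list[int], image_shape: tuple[int, int],
                       seed: int = 0, max_attempts: int = 500) -> np.ndarray:
    """Binary mask whose 8-connected components have exactly the requested
    pixel counts, placed so that no two blobs touch (8-connectivity)."""
    rows, cols = image_shape
    mask = np.zeros((rows, cols), dtype=bool)
    rng = np.random.default_rng(seed)

    def _shape(k: int) -> np.ndarray:
        cells = {(0, 0)}
        while len(cells) < k:
            ordered = sorted(cells)
            r, c = ordered[rng.integers(len(ordered))]
            dr, dc = [(1, 0), (-1, 0), (0, 1), (0, -1)][rng.integers(4)]
            cells.add((r + dr, c + dc))
        arr = np.array(sorted(cells))
        return arr - arr.min(axis=0)

    for k in sorted(blob_sizes, reverse=True):
        if k < 1:
            raise ParameterError("blob sizes must be >= 1")
        placed = False
        for _ in range(max_attempts):
            shape = _shape(int(k))
            h, w = shape.max(axis=0) + 1
            if h > rows or w > cols:
                continue
            r0 = int(rng.integers(0, rows - h + 1))
            c0 = int(rng.integers(0, cols - w + 1))
            px = shape + (r0, c0)
            ok = True
            for r, c in px:
                rl, rh = max(0, r - 1), min(rows, r + 2)
                cl, ch = max(0, c - 1), min(cols, c + 2)
                if mask[rl:rh, cl:ch].any():
                    ok = False
                    break
            if ok:
                mask[px[:, 0], px[:, 1]] = True
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place a {k}-pixel blob in {image_shape} without contact")
    return mask
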