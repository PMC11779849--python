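"""FRAP (fluorescence recovery after photobleaching) kinetics.

A junctional region is bleached and its background-subtracted intensity,
normalized to the pre-bleach mean, recovers as

    y(t) = A · (1 − exp(−k · (t − t0)))

where A is the mobile fraction, k the recovery rate (s⁻¹) and t0 the bleach
time.  The half-recovery time is t½ = ln(2)/k.  Only fits with R² strictly
above the configured gate (default 0.7) enter condition summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import AnalysisError, FormatError, NormalizationError

LN2 = float(np.log(2.0))


@dataclass
class RecoveryTrace:
    """One raw FRAP intensity trace (arbitrary units) with its background."""

    time: np.ndarray              # s
    intensity: np.ndarray         # a.u.
    background: np.ndarray | float
    bleach_index: int             # index of the first post-bleach frame
    trace_id: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.time.shape != self.intensity.shape:
            raise AnalysisError("time and intensity must be aligned")
        if not (0 < self.bleach_index < self.time.size):
            raise AnalysisError("bleach_index out of range")
        if self.bleach_index < 3:
            raise AnalysisError("need at least 3 pre-bleach frames")

    @property
    def background_array(self) -> np.ndarray:
        bg = self.background
        if np.isscalar(bg):
            return np.full_like(self.intensity, float(bg))
        return np.asarray(bg, dtype=float)


@dataclass
class RecoveryFit:
    A: float          # mobile fraction
    k: float          # s⁻¹
    t0: float         # s
    r_squared: float
    t_half: float     # s, = ln2/k
    included: bool
    trace_id: str = ""
    converged: bool = True


def recovery_model(t, A: float, k: float, t0: float):
    """The single-exponential recovery curve, clamped at 0 before t0."""
    t = np.asarray(t, dtype=float)
    return A * (1.0 - np.exp(-k * np.clip(t - t0, 0.0, None)))


def normalize_trace(raw: RecoveryTrace) -> np.ndarray:
    """Background-subtract and scale so that the pre-bleach mean is exactly 1.

    y(t) = (I(t) − bg(t)) / (mean_pre(I − bg)); raises when the pre-bleach
    signal does not exceed the background.
    """
    corrected = raw.intensity - raw.background_array
    pre = corrected[: raw.bleach_index]
    pre_mean = float(pre.mean())
    if pre_mean <= 0:
        raise NormalizationError("pre-bleach intensity does not exceed background")
    return corrected / pre_mean


def fit_recovery(y: np.ndarray, t: np.ndarray, bleach_index: int,
                 r2_min: float = 0.7, trace_id: str = "") -> RecoveryFit:
    """Nonlinear least squares of the recovery model on post-bleach points.

    Initialization: A from the tail plateau, k = 3/(post-bleach span), t0 at
    the bleach time; t0 is fitted within ±2 frames of the bleach.  R² is
    computed on the fitted (post-bleach) points only, and the fit is included
    iff R² is strictly above ``r2_min``.
    """
    y = np.asarray(y, dtype=float)
    t = np.asarray(t, dtype=float)
    tp = t[bleach_index:]
    yp = y[bleach_index:]
    if tp.size < 10:
        raise AnalysisError(f"need >= 10 post-bleach points, got {tp.size}")
    t_bleach = float(tp[0])
    dt = float(np.median(np.diff(tp)))
    span = float(tp[-1] - t_bleach)
    a0 = float(np.clip(np.mean(yp[-max(3, yp.size // 10):]), 1e-3, 1.5))
    bounds = ([1e-6, 1e-6, t_bleach - 2 * dt], [1.5, 1e3, t_bleach + 2 * dt])

    best = None
    for k0 in (3.0 / span, 0.3 / span, 30.0 / span):
        try:
            popt, _ = optimize.curve_fit(
                recovery_model, tp, yp, p0=[a0, k0, t_bleach],
                bounds=bounds, maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        resid = yp - recovery_model(tp, *popt)
        cost = float(resid @ resid)
        if best is None or cost < best[1]:
            best = (popt, cost)
    if best is None:
        return RecoveryFit(A=np.nan, k=np.nan, t0=np.nan, r_squared=-np.inf,
                           t_half=np.nan, included=False, trace_id=trace_id,
                           converged=False)
    (a_hat, k_hat, t0_hat), ss_res = best
    ss_tot = float(np.sum((yp - yp.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else 0.0)
    return RecoveryFit(A=float(a_hat), k=float(k_hat), t0=float(t0_hat),
                       r_squared=float(r2), t_half=LN2 / float(k_hat),
                       included=bool(r2 > r2_min), trace_id=trace_id)


def analyze_trace(raw: RecoveryTrace, r2_min: float = 0.7) -> RecoveryFit:
    """Normalize then fit one raw trace."""
    y = normalize_trace(raw)
    return fit_recovery(y, raw.time, raw.bleach_index, r2_min=r2_min,
                        trace_id=raw.trace_id)


def summarize_condition(fits: list[RecoveryFit]) -> dict:
    """Mean ± SD of mobile fraction and t½ over included fits only."""
    included = [f for f in fits if f.included]
    if not included:
        raise AnalysisError("no fits pass the R² gate; nothing to summarize")
    a = np.array([f.A for f in included])
    th = np.array([f.t_half for f in included])
    sd = lambda v: float(np.std(v, ddof=1)) if v.size > 1 else 0.0
    return {
        "n_included": len(included),
        "n_excluded": len(fits) - len(included),
        "excluded_ids": [f.trace_id for f in fits if not f.included],
        "mobile_fraction_mean": float(a.mean()),
        "mobile_fraction_sd": sd(a),
        "t_half_mean_s": float(th.mean()),
        "t_half_sd_s": sd(th),
    }


# ---------------------------------------------------------------------------
# On-disk format: long TSV (trace_id, time_s, intensity, background, phase)
# ---------------------------------------------------------------------------

_FRAP_COLUMNS = ["trace_id", "time_s", "intensity", "background", "phase"]


def read_frap_traces(path: str | Path) -> list[RecoveryTrace]:
    from .io import _numeric_column, _read_tsv  # shared TSV plumbing

    path = Path(path)
    _, df = _read_tsv(path)
    missing = [c for c in _FRAP_COLUMNS if c not in df.columns]
    if df.empty or missing:
        raise FormatError(f"{path}: FRAP TSV requires columns {_FRAP_COLUMNS}")
    time = _numeric_column(df, "time_s", path)
    inten = _numeric_column(df, "intensity", path)
    bg = _numeric_column(df, "background", path)
    traces = []
    for tid in df["trace_id"].drop_duplicates():
        m = (df["trace_id"] == tid).to_numpy()
        phases = df.loc[m, "phase"].to_numpy()
        post = np.nonzero(phases == "post")[0]
        if post.size == 0:
            raise FormatError(f"{path}: trace {tid!r} has no post-bleach frames")
        traces.append(RecoveryTrace(
            time=time[m], intensity=inten[m], background=bg[m],
            bleach_index=int(post[0]), trace_id=str(tid)))
    return traces


def write_frap_traces(traces: list[RecoveryTrace], path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_FRAP_COLUMNS) + "\n")
        for tr in traces:
            bg = tr.background_array
            for i, (t, v, b) in enumerate(zip(tr.time, tr.intensity, bg)):
                phase = "pre" if i < tr.bleach_index else "post"
                fh.write(f"{tr.trace_id}\t{t:.8g}\t{v:.8g}\t{b:.8g}\t{phase}\n")
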