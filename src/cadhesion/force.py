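"""Single-molecule AFM force-spectroscopy analysis.

The analysis chain mirrors standard constant-velocity force-spectroscopy
practice: calibrate the cantilever spring constant by the thermal-fluctuation
(equipartition) method, detect rupture events on retract traces, validate
each event by a worm-like-chain (WLC) fit to the preceding tether stretch,
gate events into specific/nonspecific, and describe the specific unbinding
forces by a Gaussian mixture whose component count is selected by BIC.

The WLC model is the Marko–Siggia interpolation

    F(x) = (k_B T / p) · [ 1/(4 (1 − x/Lc)²) − 1/4 + x/Lc ]

with persistence length ``p`` (nm), contour length ``Lc`` (nm), extension
``x`` (nm) and force in pN.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import warnings

import numpy as np
from scipy import optimize
from sklearn.exceptions import ConvergenceWarning
from sklearn.mixture import GaussianMixture

from .errors import AnalysisError, CalibrationError, ParameterError
from .io import ForceCurve
from .units import thermal_energy

#: Lower floor for a mixture component's standard deviation, pN.
SD_FLOOR_PN = 0.5


# ---------------------------------------------------------------------------
# Models and calibration
# ---------------------------------------------------------------------------

def wlc_force(x, p: float, lc: float, temperature: float = 298.15):
    """Marko–Siggia WLC force (pN) at extension ``x`` (nm).

    Valid for 0 <= x < Lc; diverges as x -> Lc.
    """
    if p <= 0 or lc <= 0:
        raise ParameterError("persistence and contour length must be positive")
    x = np.asarray(x, dtype=float)
    z = x / lc
    if np.any(z >= 1):
        raise ParameterError("extension must be below the contour length")
    return (thermal_energy(temperature) / p) * (0.25 / (1.0 - z) ** 2 - 0.25 + z)


def wlc_extension_at_force(f: float, p: float, lc: float,
                           temperature: float = 298.15) -> float:
    """Invert the WLC: the extension (nm) at which the model force equals ``f``."""
    if f <= 0:
        raise ParameterError("force must be positive")
    return float(optimize.brentq(
        lambda x: float(wlc_force(x, p, lc, temperature)) - f, 1e-9, lc * (1 - 1e-9)
    ))


@dataclass
class SpringCalibration:
    k: float            # pN/nm
    temperature: float  # K
    n_samples: int


def calibrate_spring_constant(deflection: np.ndarray,
                              temperature: float = 298.15) -> SpringCalibration:
    """Thermal-fluctuation calibration: k = k_B·T / var(deflection).

    ``deflection`` is the free-cantilever deflection signal in nm; it is
    mean-centred internally.  Requires at least 100 samples.
    """
    d = np.asarray(deflection, dtype=float)
    if d.size < 100:
        raise AnalysisError(f"need >= 100 deflection samples, got {d.size}")
    var = float(np.var(d - d.mean(), ddof=1))
    if var <= 0:
        raise CalibrationError("zero deflection variance; cannot calibrate")
    return SpringCalibration(k=thermal_energy(temperature) / var,
                             temperature=temperature, n_samples=int(d.size))


# ---------------------------------------------------------------------------
# Event detection
# ---------------------------------------------------------------------------

class CandidateEvent(NamedTuple):
    index: int
    force: float  # pN, relative to baseline


def _moving_average(y: np.ndarray, w: int) -> np.ndarray:
    if w <= 1:
        return y.astype(float)
    kernel = np.ones(w) / w
    pad = np.concatenate([np.full(w // 2, y[0]), y, np.full(w - 1 - w // 2, y[-1])])
    return np.convolve(pad, kernel, mode="valid")


def detect_rupture_events(curve: ForceCurve, smooth: int = 5,
                          lookahead: int = 5) -> list[CandidateEvent]:
    """Locate downward force steps (tether ruptures) on a retract trace.

    The baseline (zero-force level and noise SD) is estimated from the final
    10% of the trace.  A candidate is a step on the lightly smoothed trace
    that drops by more than 3× the baseline noise SD within ``lookahead``
    samples, starting from a force itself significantly above baseline.
    Forces are reported relative to the baseline.
    """
    f = np.asarray(curve.force, dtype=float)
    n = f.size
    n_base = max(2, n // 10)
    if n < 10 * 2:
        raise AnalysisError("trace shorter than the baseline window")
    base = f[-n_base:]
    mu_b = float(base.mean())
    sd_b = float(base.std(ddof=1))
    tau = max(3.0 * sd_b, 1e-9)

    s = _moving_average(f, smooth)
    drops = np.full(n, -np.inf)
    for i in range(n - 1):
        j = min(n, i + 1 + lookahead)
        drops[i] = s[i] - s[i + 1:j].min()
    candidate = (drops > tau) & ((f - mu_b) > tau)

    events: list[CandidateEvent] = []
    idx = np.nonzero(candidate)[0]
    if idx.size == 0:
        return events
    # group nearby candidate samples into single events
    groups: list[list[int]] = [[int(idx[0])]]
    for i in idx[1:]:
        if i - groups[-1][-1] <= lookahead:
            groups[-1].append(int(i))
        else:
            groups.append([int(i)])
    for g in groups:
        lo = max(0, g[0] - smooth // 2)
        hi = min(n, g[-1] + 2)
        peak = lo + int(np.argmax(f[lo:hi]))
        events.append(CandidateEvent(index=peak, force=float(f[peak] - mu_b)))
    events.sort(key=lambda e: e.index)
    return events


# ---------------------------------------------------------------------------
# WLC fitting and specificity gating
# ---------------------------------------------------------------------------

@dataclass
class WlcFit:
    p: float             # persistence length, nm
    lc: float            # contour length, nm
    residual_rms: float  # pN
    r_squared: float
    converged: bool = True


def fit_wlc(extension: np.ndarray, force: np.ndarray,
            temperature: float = 298.15, lc_max: float | None = None) -> WlcFit:
    """Least-squares Marko–Siggia fit over (p, Lc).

    Runs a small grid of restarts and keeps the best solution.  A fit that
    fails to converge is returned flagged (``converged=False``) rather than
    raising, so the downstream gate can reject the event.
    """
    x = np.asarray(extension, dtype=float)
    f = np.asarray(force, dtype=float)
    if x.size < 10:
        return WlcFit(p=np.nan, lc=np.nan, residual_rms=np.inf,
                      r_squared=0.0, converged=False)
    xmax = float(x.max())
    if xmax <= 0:
        return WlcFit(p=np.nan, lc=np.nan, residual_rms=np.inf,
                      r_squared=0.0, converged=False)
    if lc_max is None:
        lc_max = 4.0 * xmax

    def residuals(theta):
        p, lc = theta
        return wlc_force(x, p, lc, temperature) - f

    best = None
    lo = [1e-3, xmax * 1.001]
    hi = [10.0, lc_max]
    for p0 in (0.1, 0.38, 1.0):
        for lc0_fac in (1.1, 1.5, 2.5):
            lc0 = min(max(xmax * lc0_fac, lo[1] * 1.01), hi[1] * 0.999)
            try:
                res = optimize.least_squares(
                    residuals, x0=[p0, lc0], bounds=(lo, hi), max_nfev=2000)
            except (ValueError, ParameterError):
                continue
            if best is None or res.cost < best.cost:
                best = res
    if best is None or not np.all(np.isfinite(best.x)):
        return WlcFit(p=np.nan, lc=np.nan, residual_rms=np.inf,
                      r_squared=0.0, converged=False)
    p_hat, lc_hat = best.x
    pred = wlc_force(x, p_hat, lc_hat, temperature)
    ss_res = float(np.sum((f - pred) ** 2))
    ss_tot = float(np.sum((f - f.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else 0.0)
    return WlcFit(p=float(p_hat), lc=float(lc_hat),
                  residual_rms=float(np.sqrt(ss_res / x.size)),
                  r_squared=float(min(max(r2, 0.0), 1.0)), converged=True)


@dataclass
class RuptureEvent:
    curve_id: str
    rupture_force: float  # pN
    wlc: WlcFit
    specific: bool


def classify_specific(event: CandidateEvent, wlc: WlcFit,
                      r2_min: float = 0.9,
                      lc_window: tuple[float, float] = (0.5, 1.5),
                      nominal_lc: float = 30.0) -> bool:
    """Specific iff the WLC fit converged, r² passes (>=) and Lc lies within
    the window around the nominal tether contour length (inclusive)."""
    if not wlc.converged or not np.isfinite(wlc.lc):
        return False
    if wlc.r_squared < r2_min:
        return False
    lo, hi = lc_window[0] * nominal_lc, lc_window[1] * nominal_lc
    return bool(lo <= wlc.lc <= hi)


def analyze_curve(curve: ForceCurve, r2_min: float = 0.9,
                  lc_window: tuple[float, float] = (0.5, 1.5),
                  nominal_lc: float = 30.0) -> RuptureEvent | None:
    """Full per-curve chain: detect events, WLC-fit the stretch preceding the
    final event, gate into specific/nonspecific.

    Returns None when no event is detected at all.  When a curve has multiple
    events the final (largest-extension) one is analyzed.
    """
    events = detect_rupture_events(curve)
    if not events:
        return None
    ev = events[-1]
    x = curve.separation[:ev.index + 1]
    # light low-pass before fitting, as instrument bandwidth limiting would do;
    # the rupture force itself is read from the raw trace
    f = _moving_average(curve.force[:ev.index + 1], 5)
    wlc = fit_wlc(x, f, temperature=curve.temperature)
    specific = classify_specific(ev, wlc, r2_min=r2_min,
                                 lc_window=lc_window, nominal_lc=nominal_lc)
    return RuptureEvent(curve_id=curve.curve_id, rupture_force=ev.force,
                        wlc=wlc, specific=specific)


def analyze_curves(curves: Sequence[ForceCurve], **kwargs) -> list[RuptureEvent]:
    out = []
    for c in curves:
        ev = analyze_curve(c, **kwargs)
        if ev is not None:
            out.append(ev)
    return out


def specific_forces(events: Sequence[RuptureEvent]) -> np.ndarray:
    return np.array([e.rupture_force for e in events if e.specific], dtype=float)


# ---------------------------------------------------------------------------
# Histogram binning and mixture modelling
# ---------------------------------------------------------------------------

def fd_bin_edges(forces: np.ndarray) -> np.ndarray:
    """Freedman–Diaconis histogram edges: width h = 2·IQR·n^(−1/3).

    Quartiles use linear interpolation.  Edges span [min, max] with the last
    bin padded past the maximum when the range is not a multiple of h.  When
    the IQR is zero the bin count falls back to the Sturges rule.
    """
    f = np.asarray(forces, dtype=float)
    n = f.size
    if n < 2:
        raise AnalysisError("need at least 2 values to bin")
    fmin, fmax = float(f.min()), float(f.max())
    if fmax == fmin:
        return np.array([fmin - 0.5, fmax + 0.5])
    q1, q3 = np.percentile(f, [25, 75])
    iqr = float(q3 - q1)
    if iqr > 0:
        h = 2.0 * iqr * n ** (-1.0 / 3.0)
        m = max(1, int(np.ceil((fmax - fmin) / h - 1e-12)))
        return fmin + h * np.arange(m + 1)
    n_bins = int(np.ceil(np.log2(n))) + 1
    return np.linspace(fmin, fmax, n_bins + 1)


@dataclass
class MixtureFit:
    components: list[tuple[float, float, float]]  # (weight, mean pN, sd pN), mean-sorted
    n: int
    bic_by_k: dict[int, float]
    selected_k: int
    bin_edges: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        w = sum(c[0] for c in self.components)
        if abs(w - 1.0) > 1e-9:
            raise AnalysisError(f"component weights sum to {w}, expected 1")
        means = [c[1] for c in self.components]
        if means != sorted(means):
            raise AnalysisError("components must be sorted by mean")


def fit_force_mixture(forces: np.ndarray, k_max: int = 4,
                      seed: int = 0) -> MixtureFit:
    """EM Gaussian-mixture fits on the raw forces for k = 1..k_max, with the
    component count selected by BIC (ties broken toward smaller k).

    Each k uses 10 EM restarts keeping the best log-likelihood.  Component
    standard deviations are floored at 0.5 pN via covariance regularization,
    so degenerate point components cannot occur.  The Freedman–Diaconis bin
    edges are attached for reporting only; the fit itself never bins.
    """
    f = np.asarray(forces, dtype=float).reshape(-1, 1)
    n = f.shape[0]
    if n < 20:
        raise AnalysisError(f"need >= 20 forces to fit a mixture, got {n}")
    if k_max < 1:
        raise ParameterError("k_max must be >= 1")
    bic_by_k: dict[int, float] = {}
    models: dict[int, GaussianMixture] = {}
    for k in range(1, k_max + 1):
        gm = GaussianMixture(
            n_components=k, covariance_type="full",
            reg_covar=SD_FLOOR_PN ** 2, n_init=10, max_iter=500,
            random_state=seed,
        )
        with warnings.catch_warnings():
            # duplicate-valued degenerate inputs trip the k-means initializer
            warnings.simplefilter("ignore", ConvergenceWarning)
            gm.fit(f)
        bic_by_k[k] = float(gm.bic(f))
        models[k] = gm
    selected_k = min(bic_by_k, key=lambda k: (bic_by_k[k], k))
    gm = models[selected_k]
    comps = sorted(
        zip(gm.weights_.ravel(), gm.means_.ravel(),
            np.sqrt(gm.covariances_.ravel())),
        key=lambda c: c[1],
    )
    weights = np.array([c[0] for c in comps])
    weights = weights / weights.sum()  # guard against 1e-12 drift
    components = [(float(w), float(m), float(s))
                  for w, (_, m, s) in zip(weights, comps)]
    return MixtureFit(components=components, n=n, bic_by_k=bic_by_k,
                      selected_k=selected_k, bin_edges=fd_bin_edges(f.ravel()))


def compare_conditions(fit_a: MixtureFit, fit_b: MixtureFit,
                       forces_a: np.ndarray, forces_b: np.ndarray) -> dict:
    """Peak table for two conditions plus a Welch two-sided t-test on the
    pooled raw forces."""
    from .quant import two_sided_t

    t, p = two_sided_t(np.asarray(forces_a, dtype=float),
                       np.asarray(forces_b, dtype=float))
    return {
        "condition_a": {"n": fit_a.n, "selected_k": fit_a.selected_k,
                        "components": [list(c) for c in fit_a.components]},
        "condition_b": {"n": fit_b.n, "selected_k": fit_b.selected_k,
                        "components": [list(c) for c in fit_b.components]},
        "t_statistic": float(t),
        "p_value": float(p),
    }
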