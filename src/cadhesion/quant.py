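"""Biochemical and imaging arithmetic.

Phos-tag phosphorylation fractions, co-immunoprecipitation association
ratios, surface-biotinylation fractions, the combined "effective" surface
cadherin statistic, connected-component aggregate sizing with pixel cutoffs,
and a thin Welch t-test reporting utility.

Band intensities arrive as a tidy table with columns
(condition, band, intensity, replicate); every ratio here is built within a
replicate and lane, so common loading factors cancel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .errors import AnalysisError, ParameterError


def _band(table: pd.DataFrame, condition: str, band: str) -> pd.Series:
    """Per-replicate intensities of one band in one condition."""
    rows = table[(table["condition"] == condition) & (table["band"] == band)]
    if rows.empty:
        raise AnalysisError(f"missing band {band!r} for condition {condition!r}")
    return rows.set_index("replicate")["intensity"]


def phospho_fraction(table: pd.DataFrame, condition: str) -> tuple[float, float]:
    """Fraction phosphorylated = phospho / (phospho + unphospho), per
    replicate; returns (mean, sd) across replicates."""
    ph = _band(table, condition, "phospho")
    un = _band(table, condition, "unphospho")
    if set(ph.index) != set(un.index):
        missing = set(ph.index) ^ set(un.index)
        raise AnalysisError(
            f"condition {condition!r}: replicates {sorted(missing)} lack one band")
    frac = (ph / (ph + un.reindex(ph.index))).to_numpy()
    sd = float(np.std(frac, ddof=1)) if frac.size > 1 else 0.0
    return float(frac.mean()), sd


def coip_ratio(table: pd.DataFrame, condition: str,
               reference_condition: str) -> tuple[float, float]:
    """Per-replicate (p120/pcad) ratio normalized to the reference condition;
    returns (mean, sd) of the normalized ratio across replicates."""
    def _ratio(cond: str) -> pd.Series:
        p120 = _band(table, cond, "p120")
        pcad = _band(table, cond, "pcad")
        if (pcad == 0).any():
            raise AnalysisError(f"zero pcad intensity in condition {cond!r}")
        return p120 / pcad.reindex(p120.index)

    r = _ratio(condition)
    ref = _ratio(reference_condition)
    norm = (r / float(ref.mean())).to_numpy()
    sd = float(np.std(norm, ddof=1)) if norm.size > 1 else 0.0
    return float(norm.mean()), sd


def surface_fraction(table: pd.DataFrame, condition: str) -> tuple[float, float]:
    """Surface-biotinylated over whole-lysate intensity, per replicate."""
    surf = _band(table, condition, "surface")
    lys = _band(table, condition, "lysate")
    if (lys == 0).any():
        raise AnalysisError(f"zero lysate intensity in condition {condition!r}")
    frac = (surf / lys.reindex(surf.index)).to_numpy()
    sd = float(np.std(frac, ddof=1)) if frac.size > 1 else 0.0
    return float(frac.mean()), sd


@dataclass
class EffectivePcad:
    condition: str
    surface_fraction: float
    p120_ratio: float
    effective: float  # normalized so the reference condition is 1


def effective_pcad(surface: dict[str, float], p120: dict[str, float],
                   reference: str) -> list[EffectivePcad]:
    """Combine surface fraction and p120 association into one statistic.

    Assuming the adapter only associates with surface-resident cadherin,
    effective = surface_fraction × p120_ratio per condition, then the whole
    set is renormalized so the reference condition equals 1.
    """
    if set(surface) != set(p120):
        raise AnalysisError(
            f"condition sets differ: {sorted(set(surface) ^ set(p120))}")
    if reference not in surface:
        raise AnalysisError(f"reference condition {reference!r} absent")
    raw = {c: surface[c] * p120[c] for c in surface}
    ref = raw[reference]
    if ref == 0:
        raise AnalysisError("reference condition has zero effective signal")
    return [EffectivePcad(condition=c, surface_fraction=surface[c],
                          p120_ratio=p120[c], effective=raw[c] / ref)
            for c in sorted(surface)]


@dataclass
class AggregateStats:
    sizes: list[int]          # pixels (bead mode) or cell counts (cell mode)
    n_aggregates: int
    mean_size: float
    mode: str
    cutoffs: dict[str, int]


_EIGHT_CONNECTED = np.ones((3, 3), dtype=int)


def aggregate_sizes(mask: np.ndarray, mode: str = "bead",
                    min_object_px: int = 30, single_cell_px: int = 40,
                    min_cells: int = 5) -> AggregateStats:
    """Size statistics of 8-connected components of a binary mask.

    bead mode: components with at least ``min_object_px`` pixels (inclusive)
    are retained and reported in pixels.  cell mode: each component's cell
    count is round(area / single_cell_px) and only aggregates with strictly
    more than ``min_cells`` cells are retained, reported in cells.
    """
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ParameterError("mask must be 2-D")
    uniq = np.unique(mask)
    if not np.all(np.isin(uniq, [0, 1])) and mask.dtype != bool:
        raise ParameterError("mask must be binary (0/1)")
    if min_object_px <= 0 or single_cell_px <= 0:
        raise ParameterError("pixel cutoffs must be positive")
    labels, n = ndimage.label(mask.astype(bool), structure=_EIGHT_CONNECTED)
    areas = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1)).astype(int)
    if mode == "bead":
        sizes = sorted(int(a) for a in areas if a >= min_object_px)
        cutoffs = {"min_object_px": min_object_px}
    elif mode == "cell":
        cells = np.rint(areas / single_cell_px).astype(int)
        sizes = sorted(int(c) for c in cells if c > min_cells)
        cutoffs = {"single_cell_px": single_cell_px, "min_cells": min_cells}
    else:
        raise ParameterError(f"mode must be bead|cell, got {mode!r}")
    mean = float(np.mean(sizes)) if sizes else 0.0
    return AggregateStats(sizes=sizes, n_aggregates=len(sizes),
                          mean_size=mean, mode=mode, cutoffs=cutoffs)


def two_sided_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Welch (unequal-variance) two-sided t-test.

    Degenerate case: both groups constant with equal means gives t = 0,
    p = 1 rather than NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise AnalysisError("each group needs at least 2 observations")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        return float(np.inf if x.mean() > y.mean() else -np.inf), 0.0
    t, p = stats.ttest_ind(x, y, equal_var=False)
    return float(t), float(p)
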