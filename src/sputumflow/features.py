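"""Classifier features from viable singlets, and sample-eligibility QC.

Two feature families are extracted from the blood tube:

* *density regions*: per event the ratio of logicle fluorescence to the
  log10 of the raw scatter area (TCPP over log10 SSC-A, viability dye over
  log10 FSC-A), partitioned into three regions (< 0.25, 0.25-0.6, > 0.6)
  and tabulated per 10,000 viable singlets;
* *quantized grids*: logicle signal split into low (< 1.5), low-mid
  (1.5-2.5), mid (2.5-3) and high (> 3) windows, giving a 4x4 grid of
  per-10K counts for CD206 x lineage pool (and EpCAM x Pan-CK in the
  epithelial tube, reported but unused by the model).

Per-10K counts are integers apportioned by largest remainder so every
region/grid sums to exactly 10,000.  Eligibility requires at least 10,000
viable singlets and at least 10 events in the lung-macrophage grid area
(CD206 mid+high x lineage low+low-mid).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

from .fcs import EventTable
from .gating import GatingResult

__all__ = [
    "DensityRegions",
    "QuantizedGrid",
    "FeatureVector",
    "SampleEligibility",
    "FeatureError",
    "density_region_counts",
    "grid_counts",
    "extract_features",
    "DEFAULT_REGION_BOUNDS",
    "DEFAULT_GRID_WINDOWS",
    "FEATURE_COLUMNS",
]

DEFAULT_REGION_BOUNDS = (0.25, 0.6)
DEFAULT_GRID_WINDOWS = (1.5, 2.5, 3.0)
PER10K = 10_000

FEATURE_COLUMNS = [
    "age", "tcpp_r3_per10k", "fvs_r2_per10k", "cd206low_linmid_per10k",
    "macrophages", "viable_singlets", "eligible",
]


class FeatureError(ValueError):
    pass


def _apportion_per10k(counts: np.ndarray) -> np.ndarray:
    """Integer per-10K counts by largest remainder; sums to exactly 10,000.

    Ties in the fractional parts break deterministically by index order.
    """
    counts = np.asarray(counts, dtype=np.int64)
    total = counts.sum()
    if total <= 0:
        raise FeatureError("no viable singlets")
    exact = counts * PER10K / total
    base = np.floor(exact).astype(np.int64)
    short = PER10K - base.sum()
    frac = exact - base
    order = np.lexsort((np.arange(frac.size), -frac))
    base[order[:short]] += 1
    return base


@dataclass
class DensityRegions:
    bounds: Tuple[float, float]
    counts_per_10k: Tuple[int, int, int]

    def __post_init__(self) -> None:
        assert sum(self.counts_per_10k) == PER10K


@dataclass
class QuantizedGrid:
    windows: Tuple[float, float, float]
    cells: np.ndarray  # (4, 4) per-10K counts, [x-window, y-window]
    raw_cells: np.ndarray  # (4, 4) raw counts

    def __post_init__(self) -> None:
        assert self.cells.shape == (4, 4)
        assert int(self.cells.sum()) == PER10K


@dataclass
class FeatureVector:
    age: float
    tcpp_r3: int
    fvs_r2: int
    cd206low_linmid: int
    macrophage_count: int
    viable_singlets: int

    def to_row(self, eligible: bool) -> Dict[str, float]:
        return {
            "age": self.age,
            "tcpp_r3_per10k": self.tcpp_r3,
            "fvs_r2_per10k": self.fvs_r2,
            "cd206low_linmid_per10k": self.cd206low_linmid,
            "macrophages": self.macrophage_count,
            "viable_singlets": self.viable_singlets,
            "eligible": bool(eligible),
        }


@dataclass
class SampleEligibility:
    enough_singlets: bool
    lung_confirmed: bool
    min_singlets: int = PER10K
    min_macrophages: int = 10

    @property
    def eligible(self) -> bool:
        return self.enough_singlets and self.lung_confirmed


def density_region_counts(t: EventTable, singlets: np.ndarray,
                          fluor_role: str, scatter_role: str,
                          bounds: Tuple[float, float] = DEFAULT_REGION_BOUNDS
                          ) -> DensityRegions:
    """Three-region per-10K tabulation of fluorescence / log10(scatter).

    The middle region is closed ([lo, hi]); the outer regions are open,
    the "< lo, lo-hi, > hi" reading of the bounds.  The scatter
    denominator uses raw (untransformed) pulse area.
    """
    if singlets.sum() == 0:
        raise FeatureError("no viable singlets")
    if t.role_scale(fluor_role) != "logicle":
        raise FeatureError(f"{fluor_role} must be on the logicle scale")
    scatter = t.get(scatter_role)[singlets]
    if np.any(scatter <= 1.0):
        raise FeatureError(
            f"{scatter_role} values <= 1 after gating; size gate not applied?"
        )
    r = t.get(fluor_role)[singlets] / np.log10(scatter)
    lo, hi = bounds
    raw = np.array([(r < lo).sum(), ((r >= lo) & (r <= hi)).sum(), (r > hi).sum()])
    per10k = _apportion_per10k(raw)
    return DensityRegions(bounds=bounds, counts_per_10k=tuple(int(v) for v in per10k))


def _window_index(values: np.ndarray, windows: Tuple[float, float, float]) -> np.ndarray:
    """0=low, 1=low-mid, 2=mid, 3=high; windows closed on the lower edge."""
    return np.searchsorted(np.asarray(windows), values, side="right")


def grid_counts(t: EventTable, singlets: np.ndarray, role_x: str, role_y: str,
                windows: Tuple[float, float, float] = DEFAULT_GRID_WINDOWS
                ) -> QuantizedGrid:
    """4x4 per-10K grid of two logicle-scale signals."""
    if singlets.sum() == 0:
        raise FeatureError("no viable singlets")
    for role in (role_x, role_y):
        if t.role_scale(role) != "logicle":
            raise FeatureError(f"{role} must be on the logicle scale")
    ix = _window_index(t.get(role_x)[singlets], windows)
    iy = _window_index(t.get(role_y)[singlets], windows)
    raw = np.bincount(ix * 4 + iy, minlength=16).reshape(4, 4)
    per10k = _apportion_per10k(raw.ravel()).reshape(4, 4)
    return QuantizedGrid(windows=windows, cells=per10k, raw_cells=raw)


def extract_features(g: GatingResult, blood: EventTable, age: float,
                     windows: Tuple[float, float, float] = DEFAULT_GRID_WINDOWS,
                     bounds: Tuple[float, float] = DEFAULT_REGION_BOUNDS,
                     lineage_mid_window: int = 2,
                     ) -> Tuple[FeatureVector, SampleEligibility]:
    """Model features and eligibility from the gated blood tube.

    ``lineage_mid_window`` indexes the lineage window counted as "mid" for
    the CD206-low sector (2 = the [2.5, 3) window).
    """
    if age <= 0:
        raise FeatureError("age must be positive")
    singlets = g.masks["viable_singlets"]
    n_singlets = int(singlets.sum())
    if n_singlets == 0:
        raise FeatureError("no viable singlets")

    tcpp = density_region_counts(blood, singlets, "TCPP", "SSC-A", bounds)
    fvs = density_region_counts(blood, singlets, "FVS510", "FSC-A", bounds)
    grid = grid_counts(blood, singlets, "CD206", "LINEAGE", windows)

    cd206low_linmid = int(grid.cells[0, lineage_mid_window])
    # lung macrophages: CD206 mid+high x lineage low+low-mid, raw count
    macrophages = int(grid.raw_cells[2:4, 0:2].sum())

    fv = FeatureVector(
        age=float(age),
        tcpp_r3=int(tcpp.counts_per_10k[2]),
        fvs_r2=int(fvs.counts_per_10k[1]),
        cd206low_linmid=cd206low_linmid,
        macrophage_count=macrophages,
        viable_singlets=n_singlets,
    )
    elig = SampleEligibility(
        enough_singlets=n_singlets >= PER10K,
        lung_confirmed=macrophages >= 10,
    )
    return fv, elig
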