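"""Automated gating cascade: viable single cells from each assay tube.

The cascade anchors a size gate on the calibration-bead cluster, removes a
corner artifact population when present, places a viability threshold on
the FVS510 dye by density tail-gating on a heuristically chosen "core
viable" subpopulation, fits a singlets polygon along the pulse-geometry
ridge, and applies two documented repair heuristics:

* when the naive singlets fit is malformed (lower-left corner below zero,
  or top-left above bottom-right), the fit is repeated on events with
  SSC-A below a temporary limit and the repaired polygon applied to all
  viable events;
* when more than a configurable fraction of singlets carry intermediate
  viability-dye signal between the natural cutoff (2.5 on the logicle
  scale) and the tail-gate threshold, and a mixture fit confirms a distinct
  upper component, the threshold is reset to the natural cutoff and the
  singlets polygon refit.

All mixture fits are seeded; the applied heuristics are logged in the
result.  Gate boundaries are closed on the kept side.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from matplotlib.path import Path as MplPath
from scipy.stats import chi2, gaussian_kde
from sklearn.mixture import GaussianMixture

from .fcs import EventTable

__all__ = [
    "GateConfig",
    "GatingResult",
    "GatingError",
    "BeadQCError",
    "ViabilityPreGateError",
    "SingletsGateError",
    "find_bead_threshold",
    "bse_gate",
    "exclude_corner_artifacts",
    "core_viable_gate",
    "viability_threshold",
    "fit_singlets_polygon",
    "refine_viability",
    "run_gating",
]


class GatingError(RuntimeError):
    """Base class for gating-stage failures; carries the stage name."""

    stage = "gating"


class BeadQCError(GatingError):
    stage = "bead_threshold"


class ViabilityPreGateError(GatingError):
    stage = "core_viable_gate"


class SingletsGateError(GatingError):
    stage = "singlets_gate"


@dataclass
class GateConfig:
    """Tunable gating parameters; defaults follow the deployed heuristics."""

    bse_upper: float = 2.5e5            # upper FSC-A/SSC-A bound, dead above
    ssc_temp_limit: float = 5.0e4       # temporary SSC-A cut for singlets repair
    tail_tolerance: float = 0.10        # density tail gate tolerance
    core_quantile: float = 0.90         # core-viable density contour
    core_quantile_fallback: float = 0.99
    core_min_fraction: float = 0.10     # triggers the fallback contour
    viability_natural_cutoff: float = 2.5   # logicle FVS510
    intermediate_pop_trigger: float = 0.10  # fraction of singlets
    bead_contour_quantile: float = 0.99     # bead cluster boundary contour
    bead_min_cluster_fraction: float = 0.20
    bead_compactness: float = 0.08      # cluster sd / data range bound
    singlet_band: Tuple[float, float] = (0.01, 0.99)  # residual quantile band
    singlet_channels: Tuple[str, str] = ("FSC-A", "FSC-W")
    max_components: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("tail_tolerance", "core_quantile", "core_quantile_fallback",
                     "core_min_fraction", "intermediate_pop_trigger"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.bse_upper <= 0:
            raise ValueError("bse_upper must be positive")


@dataclass
class GatingResult:
    """Nested stage masks, derived thresholds and the heuristics log."""

    masks: Dict[str, np.ndarray]
    fsc_min: float
    viability_threshold: float
    singlets_polygon: np.ndarray
    heuristics_applied: List[str] = field(default_factory=list)
    seed: int = 0

    STAGES = ("bead_size_exclusion", "non_debris", "viable", "viable_singlets")

    @property
    def counts(self) -> Dict[str, int]:
        return {k: int(v.sum()) for k, v in self.masks.items()}

    def assert_nested(self) -> None:
        order = self.STAGES
        for inner, outer in zip(order[1:], order[:-1]):
            if np.any(self.masks[inner] & ~self.masks[outer]):
                raise AssertionError(f"mask nesting violated: {inner} not in {outer}")

    def to_dict(self) -> dict:
        return {
            "counts": self.counts,
            "fsc_min": self.fsc_min,
            "viability_threshold": self.viability_threshold,
            "singlets_polygon": np.asarray(self.singlets_polygon).tolist(),
            "heuristics_applied": list(self.heuristics_applied),
            "seed": self.seed,
            "masks_rle": {k: _rle_encode(v) for k, v in self.masks.items()},
        }


def _rle_encode(mask: np.ndarray) -> List[int]:
    """Run lengths of a boolean mask, starting with a False run (may be 0)."""
    m = np.asarray(mask, dtype=bool)
    if m.size == 0:
        return []
    changes = np.flatnonzero(np.diff(m.astype(np.int8))) + 1
    bounds = np.concatenate(([0], changes, [m.size]))
    runs = np.diff(bounds).tolist()
    if m[0]:
        runs = [0] + runs
    return [int(r) for r in runs]


def rle_decode(runs: List[int], n: int) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    pos, val = 0, False
    for r in runs:
        if val:
            mask[pos:pos + r] = True
        pos += r
        val = not val
    return mask


# ---------------------------------------------------------------------------
# mixture helpers

def _fit_gmm_bic(data: np.ndarray, max_k: int, seed: int) -> GaussianMixture:
    """Gaussian mixture with BIC model selection over 1..max_k components."""
    best, best_bic = None, np.inf
    for k in range(1, max_k + 1):
        try:
            gm = GaussianMixture(n_components=k, covariance_type="full",
                                 random_state=seed, n_init=2,
                                 reg_covar=1e-3).fit(data)
        except ValueError:
            continue
        if not gm.converged_:
            continue
        bic = gm.bic(data)
        if bic < best_bic:
            best, best_bic = gm, bic
    if best is None:
        raise ViabilityPreGateError("mixture fit failed to converge")
    return best


def _mahalanobis_sq(data: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    diff = data - mean
    inv = np.linalg.inv(cov)
    return np.einsum("ij,jk,ik->i", diff, inv, diff)


# ---------------------------------------------------------------------------
# stage operations

def find_bead_threshold(beads: EventTable, cfg: GateConfig = GateConfig()) -> float:
    """Lower FSC-A boundary of the dominant calibration-bead cluster.

    A 2-D mixture on (FSC-A, SSC-A) identifies the dominant cluster; the
    returned threshold is the lower FSC-A extent of its
    ``bead_contour_quantile`` density contour.  A tube whose largest
    cluster is either too small (< ``bead_min_cluster_fraction`` of
    events) or not compact fails bead QC.
    """
    data = np.column_stack([beads.get("FSC-A"), beads.get("SSC-A")])
    if data.shape[0] < 50:
        raise BeadQCError("bead tube QC failure: too few bead events")
    gm = _fit_gmm_bic(data, cfg.max_components, cfg.seed)
    weights = gm.weights_
    order = np.argsort(weights)[::-1]
    ranges = data.max(axis=0) - data.min(axis=0)
    range_geo = float(np.sqrt(np.prod(np.maximum(ranges, 1.0))))
    # a bead cluster a couple of percent of full scale is always compact,
    # whatever the observed range (noise-free tubes shrink the range)
    compact_limit = max(cfg.bead_compactness * range_geo, 0.02 * 2.62144e5)
    for idx in order:
        if weights[idx] < cfg.bead_min_cluster_fraction:
            break
        cov = gm.covariances_[idx]
        sd_geo = float(np.sqrt(np.prod(np.sqrt(np.maximum(np.diag(cov), 1e-12)))))
        if sd_geo <= compact_limit:
            mean_fsc = float(gm.means_[idx][0])
            sd_fsc = float(np.sqrt(max(cov[0, 0], 0.0)))
            c = float(np.sqrt(chi2.ppf(cfg.bead_contour_quantile, df=2)))
            return max(mean_fsc - c * sd_fsc, 0.0)
    raise BeadQCError(
        "bead tube QC failure: no compact cluster holding "
        f">= {cfg.bead_min_cluster_fraction:.0%} of bead events"
    )


def bse_gate(t: EventTable, fsc_min: float, cfg: GateConfig = GateConfig()) -> np.ndarray:
    """Bead size exclusion gate; closed bounds on the kept side."""
    fsc = t.get("FSC-A")
    ssc = t.get("SSC-A")
    return (fsc >= fsc_min) & (fsc <= cfg.bse_upper) & (ssc <= cfg.bse_upper)


def exclude_corner_artifacts(t: EventTable, mask_in: np.ndarray,
                             cfg: GateConfig = GateConfig()) -> np.ndarray:
    """Remove the detached high-FSC-H / low-SSC-H corner population.

    A mixture component qualifies as the corner artifact when its FSC-H
    centroid sits in the top quartile of the observed FSC-H range while
    its SSC-H centroid lies below the 5th percentile of SSC-H.  Without
    such a component the mask is returned unchanged.
    """
    if mask_in.sum() == 0:
        return mask_in.copy()
    fsch = t.get("FSC-H")[mask_in]
    ssch = t.get("SSC-H")[mask_in]
    data = np.column_stack([fsch, ssch])
    try:
        gm = _fit_gmm_bic(data, cfg.max_components, cfg.seed)
    except ViabilityPreGateError:
        return mask_in.copy()
    # corner region: near the top of the FSC-H scale, at the very bottom of
    # SSC-H; absolute anchors keep the degenerate corner-only case detectable
    fsch_cut = 0.75 * 2.62144e5
    ssch_cut = max(float(np.percentile(ssch, 5.0)), 0.005 * 2.62144e5)
    corner_components = [
        k for k in range(gm.n_components)
        if gm.means_[k][0] > fsch_cut and gm.means_[k][1] < ssch_cut
    ]
    if not corner_components:
        return mask_in.copy()
    assign = gm.predict(data)
    drop = np.isin(assign, corner_components)
    out = mask_in.copy()
    idx = np.flatnonzero(mask_in)
    out[idx[drop]] = False
    if out.sum() == 0:
        warnings.warn("corner-artifact exclusion removed every event")
    return out


def core_viable_gate(t: EventTable, non_debris: np.ndarray,
                     cfg: GateConfig = GateConfig()
                     ) -> Tuple[np.ndarray, List[str]]:
    """Temporary low-scatter gate retaining mostly live cells.

    Fits a mixture on (FSC-H, SSC-H) of non-debris events, selects the
    component with the lowest SSC-H centroid and keeps events inside its
    ``core_quantile`` density contour; falls back to the more inclusive
    contour when the gate captures too small a fraction.
    """
    if non_debris.sum() == 0:
        raise ViabilityPreGateError("viability pre-gate failure: no non-debris events")
    tags: List[str] = []
    data = np.column_stack([t.get("FSC-H")[non_debris], t.get("SSC-H")[non_debris]])
    gm = _fit_gmm_bic(data, cfg.max_components, cfg.seed)
    # ignore trace components when picking the low-scatter candidate
    candidates = [k for k in range(gm.n_components) if gm.weights_[k] >= 0.02]
    low = min(candidates, key=lambda k: gm.means_[k][1])
    d2 = _mahalanobis_sq(data, gm.means_[low], gm.covariances_[low])
    inside = d2 <= chi2.ppf(cfg.core_quantile, df=2)
    if inside.mean() < cfg.core_min_fraction:
        inside = d2 <= chi2.ppf(cfg.core_quantile_fallback, df=2)
        tags.append("core_quantile_fallback")
    mask = np.zeros_like(non_debris)
    mask[np.flatnonzero(non_debris)[inside]] = True
    return mask, tags


def viability_threshold(t: EventTable, core_viable_singlets: np.ndarray,
                        cfg: GateConfig = GateConfig()) -> float:
    """Density tail gate on logicle FVS510 of the core viable singlets.

    The threshold is the smallest value above the dominant density mode at
    which the kernel density falls to ``tail_tolerance`` times the mode
    density; viable events lie to its left.
    """
    n = int(core_viable_singlets.sum())
    if n < 100:
        raise ViabilityPreGateError(
            f"viability pre-gate failure: only {n} core viable singlets"
        )
    values = t.get("FVS510")[core_viable_singlets]
    if float(np.std(values)) < 1e-9:
        raise ViabilityPreGateError("degenerate FVS510 signal (zero variance)")
    kde = gaussian_kde(values, bw_method="silverman")
    bw = float(kde.factor * np.std(values))
    grid = np.linspace(values.min() - 3 * bw, values.max() + 3 * bw, 1024)
    dens = kde(grid)
    mode_idx = int(np.argmax(dens))
    peak = dens[mode_idx]
    below = np.flatnonzero(dens[mode_idx:] <= cfg.tail_tolerance * peak)
    if below.size == 0:
        return float(grid[-1])
    return float(grid[mode_idx + below[0]])


def _polygon_from_fit(x: np.ndarray, y: np.ndarray, x_left: float,
                      cfg: GateConfig) -> np.ndarray:
    """Least-squares ridge line with a robust residual band, top-right
    corner forced to (bse_upper, bse_upper).

    The band half-widths are set from the median and MAD of the residuals
    at the normal quantiles of ``singlet_band``, so a few percent of
    doublet outliers cannot stretch the band, while a grossly skewed fit
    (inflated residual spread) still trips the malformation check.
    """
    from scipy.stats import norm as _norm
    beta, alpha = np.polyfit(x, y, 1)
    resid = y - (alpha + beta * x)
    med = float(np.median(resid))
    mad = float(np.median(np.abs(resid - med)))
    sigma = max(1.4826 * mad, 1e-9)
    q_lo = med + _norm.ppf(cfg.singlet_band[0]) * sigma
    q_hi = med + _norm.ppf(cfg.singlet_band[1]) * sigma
    x_right = cfg.bse_upper

    def line(xv: float) -> float:
        return alpha + beta * xv

    ll = (x_left, line(x_left) + q_lo)
    lr = (x_right, line(x_right) + q_lo)
    ur = (x_right, cfg.bse_upper)
    ul = (x_left, line(x_left) + q_hi)
    return np.array([ll, lr, ur, ul])


def _polygon_malformed(poly: np.ndarray) -> bool:
    ll, lr, ur, ul = poly
    return (ll[1] < 0.0) or (ul[1] > lr[1])


def polygon_mask(t: EventTable, poly: np.ndarray, base: np.ndarray,
                 channels: Tuple[str, str]) -> np.ndarray:
    pts = np.column_stack([t.get(channels[0]), t.get(channels[1])])
    # implicit closure: CLOSEPOLY would consume the last vertex
    inside = MplPath(poly).contains_points(pts, radius=1e-9)
    return base & inside


def fit_singlets_polygon(t: EventTable, viable: np.ndarray,
                         cfg: GateConfig = GateConfig()
                         ) -> Tuple[np.ndarray, List[str]]:
    """Quadrilateral around the singlet pulse-geometry ridge.

    Fit on the configured channel pair (default FSC-A vs FSC-W); when the
    naive fit is malformed, refit on the SSC-A-restricted subset and apply
    to the full viable population.
    """
    if viable.sum() < 100:
        raise SingletsGateError("singlets gate failure: too few viable events")
    cx, cy = cfg.singlet_channels
    x_all = t.get(cx)[viable]
    y_all = t.get(cy)[viable]
    x_left = float(x_all.min())
    tags: List[str] = []
    poly = _polygon_from_fit(x_all, y_all, x_left, cfg)
    if _polygon_malformed(poly):
        tags.append("ssc_temp_gate")
        keep = t.get("SSC-A")[viable] <= cfg.ssc_temp_limit
        if keep.sum() < 100:
            raise SingletsGateError(
                "singlets gate failure: SSC-A-restricted refit has too few events"
            )
        poly = _polygon_from_fit(x_all[keep], y_all[keep], x_left, cfg)
        if _polygon_malformed(poly):
            raise SingletsGateError("singlets gate failure: refit still malformed")
    return poly, tags


def refine_viability(t: EventTable, singlets: np.ndarray, threshold: float,
                     viable_parent: np.ndarray,
                     cfg: GateConfig = GateConfig()
                     ) -> Tuple[float, np.ndarray, np.ndarray, List[str]]:
    """Reset the viability threshold to the natural cutoff when warranted.

    When a population representing more than ``intermediate_pop_trigger``
    of singlets lies between the natural cutoff and the tail-gate
    threshold, and a two-component mixture confirms a distinct upper
    component, the cutoff replaces the tail-gate threshold and the
    singlets polygon is refit on the restricted viable set.

    Returns (threshold, viable mask, singlets polygon or None, tags).
    """
    tags: List[str] = []
    cutoff = cfg.viability_natural_cutoff
    if threshold <= cutoff or singlets.sum() == 0:
        return threshold, viable_parent.copy(), None, tags
    fvs = t.get("FVS510")[singlets]
    frac_mid = float(np.mean((fvs > cutoff) & (fvs <= threshold)))
    if frac_mid <= cfg.intermediate_pop_trigger:
        return threshold, viable_parent.copy(), None, tags
    gm = GaussianMixture(n_components=2, random_state=cfg.seed,
                         n_init=2).fit(fvs.reshape(-1, 1))
    means = np.sort(gm.means_.ravel())
    sds = np.sqrt(gm.covariances_.ravel())
    distinct = (means[1] > cutoff) and (means[1] - means[0] > 1.5 * float(sds.mean())) \
        and float(gm.weights_.min()) > 0.05
    # a "singlet" population living (almost) wholly above the natural cutoff
    # (e.g. a sample of only dying cells) also warrants the reset
    wholly_high = float(np.mean(fvs <= cutoff)) < 0.05
    if not (distinct or wholly_high):
        return threshold, viable_parent.copy(), None, tags
    tags.append("viability_reset")
    new_viable = viable_parent & (t.get("FVS510") <= cutoff)
    poly, poly_tags = fit_singlets_polygon(t, new_viable, cfg)
    tags.extend(poly_tags)
    return cutoff, new_viable, poly, tags


# ---------------------------------------------------------------------------
# orchestration

def run_gating(tubes: Dict[str, EventTable], cfg: GateConfig = GateConfig(),
               assay: str = "blood") -> GatingResult:
    """Execute the full cascade on one assay tube.

    ``tubes`` must contain ``"beads"`` and the assay tube; fluorescence of
    the assay tube must already be compensated and on the logicle scale.
    Temporary gates (core viable, provisional singlets) condition the tail
    gate but are not part of the final mask chain.
    """
    if "beads" not in tubes or assay not in tubes:
        raise GatingError(f"run_gating needs 'beads' and {assay!r} tubes")
    t = tubes[assay]
    heuristics: List[str] = []

    fsc_min = find_bead_threshold(tubes["beads"], cfg)
    bse = bse_gate(t, fsc_min, cfg)
    non_debris = exclude_corner_artifacts(t, bse, cfg)
    if non_debris.sum() < bse.sum():
        heuristics.append("corner_artifacts_excluded")

    core, core_tags = core_viable_gate(t, non_debris, cfg)
    heuristics.extend(core_tags)
    prov_poly, prov_tags = fit_singlets_polygon(t, core, cfg)
    heuristics.extend(f"provisional_{tag}" for tag in prov_tags)
    core_singlets = polygon_mask(t, prov_poly, core, cfg.singlet_channels)

    thr = viability_threshold(t, core_singlets, cfg)
    viable = non_debris & (t.get("FVS510") <= thr)

    poly, poly_tags = fit_singlets_polygon(t, viable, cfg)
    heuristics.extend(poly_tags)
    singlets = polygon_mask(t, poly, viable, cfg.singlet_channels)

    thr2, viable2, poly2, ref_tags = refine_viability(t, singlets, thr, viable, cfg)
    heuristics.extend(ref_tags)
    if poly2 is not None:
        poly, viable, thr = poly2, viable2, thr2
        singlets = polygon_mask(t, poly, viable, cfg.singlet_channels)

    result = GatingResult(
        masks={
            "bead_size_exclusion": bse,
            "non_debris": non_debris,
            "viable": viable,
            "viable_singlets": singlets,
        },
        fsc_min=fsc_min,
        viability_threshold=thr,
        singlets_polygon=poly,
        heuristics_applied=heuristics,
        seed=cfg.seed,
    )
    result.assert_nested()
    return result
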