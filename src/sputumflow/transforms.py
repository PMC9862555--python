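"""Logicle (biexponential) display transform and spillover compensation.

The logicle scale maps compensated fluorescence, including moderately
negative values, onto display decades.  It is defined as the inverse of the
biexponential

    B(y) = a * exp(b*y) - c * exp(-d*y) - f ,   y in [0, 1]

with parameters chosen from (T, W, M, A) so that B(1) = T (top of scale
maps to M decades), the scale is quasi-linear of half-width W decades
around zero, and A extra negative decades are displayed.  The forward
transform is computed by vectorized bisection on the strictly increasing
B; display values are scaled so that x = T maps to exactly M.

Spillover compensation is the usual linear-algebra step: observed
fluorescence = true fluorescence @ S, so compensation multiplies by the
inverse of the spillover matrix S.  S itself is derived de novo from
single-stain control tubes (median positive minus unstained baseline,
normalized to a unit diagonal).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy.optimize import brentq
from sklearn.mixture import GaussianMixture

from .fcs import EventTable

__all__ = [
    "LogicleParams",
    "logicle",
    "inverse_logicle",
    "logicle_table",
    "SpilloverMatrix",
    "derive_spillover",
    "compensate",
    "UninformativeControlError",
]


@dataclass(frozen=True)
class LogicleParams:
    """Parameters of the logicle scale.

    T : top of scale (linear units); M : total display decades;
    W : linearization half-width in decades; A : additional negative decades.
    """

    T: float = 262144.0
    M: float = 4.5
    W: float = 0.5
    A: float = 0.0

    def __post_init__(self) -> None:
        if not (self.T > 0 and self.M > 0 and self.W >= 0 and self.A >= 0):
            raise ValueError("require T > 0, M > 0, W >= 0, A >= 0")
        if 2 * self.W + self.A > self.M:
            raise ValueError("2W + A must not exceed M")


def _biex_coeffs(p: LogicleParams):
    """Solve the biexponential coefficients (a, b, c, d, f) for p."""
    m_total = p.M + p.A
    b = m_total * np.log(10.0)
    w = p.W / m_total
    x2 = p.A / m_total
    x1 = x2 + w
    x0 = x2 + 2.0 * w
    if w == 0.0:
        d = b
    else:
        # root of 2 ln(d/b) + w (d + b) = 0 in (0, b)
        d = brentq(lambda dd: 2.0 * (np.log(dd) - np.log(b)) + w * (dd + b),
                   1e-12, b, xtol=1e-14, rtol=1e-15)
    c_a = np.exp(x0 * (b + d))
    f_a = np.exp(b * x1) - c_a * np.exp(-d * x1)
    a = p.T / ((np.exp(b) - f_a) - c_a * np.exp(-d))
    c = c_a * a
    f = f_a * a
    return a, b, c, d, f, x1


def _biex(y: np.ndarray, coeffs) -> np.ndarray:
    a, b, c, d, f, _ = coeffs
    return a * np.exp(b * y) - c * np.exp(-d * y) - f


def inverse_logicle(values, p: LogicleParams = LogicleParams()) -> np.ndarray:
    """Display decades -> linear signal (the biexponential)."""
    y = np.asarray(values, dtype=np.float64)
    coeffs = _biex_coeffs(p)
    # display = y_internal * (M + A) - A
    return _biex((y + p.A) / (p.M + p.A), coeffs)


def logicle(values, p: LogicleParams = LogicleParams()) -> np.ndarray:
    """Linear signal -> display decades; strictly monotone; T maps to M.

    Non-finite inputs raise, listing the offending indices.
    """
    x = np.asarray(values, dtype=np.float64)
    bad = np.flatnonzero(~np.isfinite(x))
    if bad.size:
        raise ValueError(f"non-finite inputs at indices {bad[:20].tolist()}")
    coeffs = _biex_coeffs(p)
    shape = x.shape
    x = x.ravel()
    # bracket: B is increasing; widen until all values are enclosed
    lo = np.full_like(x, -1.0)
    hi = np.full_like(x, 2.0)
    for _ in range(60):
        flo = _biex(lo, coeffs) > x
        fhi = _biex(hi, coeffs) < x
        if not (flo.any() or fhi.any()):
            break
        lo[flo] *= 2.0
        hi[fhi] *= 2.0
    for _ in range(90):
        mid = 0.5 * (lo + hi)
        below = _biex(mid, coeffs) < x
        lo = np.where(below, mid, lo)
        hi = np.where(below, hi, mid)
    y = 0.5 * (lo + hi)
    return (y * (p.M + p.A) - p.A).reshape(shape)


def logicle_table(t: EventTable, roles: Sequence[str],
                  params: Optional[Dict[str, LogicleParams]] = None,
                  default: LogicleParams = LogicleParams()) -> EventTable:
    """Apply the logicle transform to fluorescence roles of a tube."""
    out = t.copy()
    for role in roles:
        p = (params or {}).get(role, default)
        out.set(role, logicle(out.get(role), p), scale="logicle")
    return out


# ---------------------------------------------------------------------------
# Spillover


class UninformativeControlError(ValueError):
    """A single-stain control has no distinguishable positive population."""


@dataclass
class SpilloverMatrix:
    """Square spillover matrix over fluorescence channel names.

    ``matrix[i, j]`` is the fraction of dye *i* signal observed in
    detector *j*; the diagonal is 1 by construction.
    """

    channel_names: List[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        n = len(self.channel_names)
        if self.matrix.shape != (n, n):
            raise ValueError("spillover matrix shape mismatch")
        if not np.allclose(np.diag(self.matrix), 1.0):
            raise ValueError("spillover diagonal must be 1")

    def inverse(self) -> np.ndarray:
        try:
            inv = np.linalg.inv(self.matrix)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"singular spillover matrix: {exc}"
            ) from exc
        if not np.all(np.isfinite(inv)):
            raise np.linalg.LinAlgError("singular spillover matrix")
        return inv

    # CSV round-trip (channel-name header row)
    def to_csv(self, path) -> None:
        header = ",".join(self.channel_names)
        np.savetxt(path, self.matrix, delimiter=",", header=header, comments="")

    @classmethod
    def from_csv(cls, path) -> "SpilloverMatrix":
        with open(path) as fh:
            names = fh.readline().strip().split(",")
        mat = np.loadtxt(path, delimiter=",", skiprows=1)
        return cls(channel_names=names, matrix=np.atleast_2d(mat))


def _positive_negative_split(values: np.ndarray, seed: int = 0):
    """Two-component 1-D Gaussian mixture split; returns (pos_mask, sep)."""
    v = values.reshape(-1, 1)
    gm = GaussianMixture(n_components=2, random_state=seed, n_init=2).fit(v)
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    hi = int(np.argmax(means))
    sep = abs(means[hi] - means[1 - hi]) / max(sds.mean(), 1e-9)
    labels = gm.predict(v)
    return labels == hi, sep


def derive_spillover(controls, unstained: EventTable,
                     seed: int = 0) -> SpilloverMatrix:
    """Derive the spillover matrix de novo from single-stain controls.

    ``controls`` maps fluorescence channel name -> its single-stain tube
    (a mapping, or a sequence of ``(name, tube)`` pairs).  Entry (i, j) is
    the background-subtracted median signal in channel j of
    channel-i-positive events, normalized so the diagonal is 1.
    """
    pairs = list(controls.items()) if hasattr(controls, "items") else list(controls)
    names = [name for name, _ in pairs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate fluorochrome assignment in controls")
    controls = dict(pairs)
    n = len(names)
    base = {nm: float(np.median(unstained.events[:, unstained.channel_names.index(nm)]))
            for nm in names}
    mat = np.eye(n)
    for i, nm in enumerate(names):
        tube = controls[nm]
        col = tube.events[:, tube.channel_names.index(nm)]
        pos, sep = _positive_negative_split(col, seed=seed)
        unst = unstained.events[:, unstained.channel_names.index(nm)]
        base_spread = 1.4826 * float(np.median(np.abs(unst - base[nm]))) + 1.0
        own = float(np.median(col[pos])) - base[nm]
        # the positive population must clear both the baseline spread and a
        # small absolute fraction of full scale
        floor = max(5.0 * base_spread, 0.002 * 2.62144e5)
        if sep < 2.0 or pos.sum() < 10 or own < floor:
            raise UninformativeControlError(
                f"uninformative control for channel {nm}: positive and negative "
                f"medians indistinguishable"
            )
        for j, other in enumerate(names):
            if i == j:
                continue
            oth = tube.events[:, tube.channel_names.index(other)]
            spill = (float(np.median(oth[pos])) - base[other]) / own
            mat[i, j] = min(max(spill, 0.0), 0.999)
    sp = SpilloverMatrix(channel_names=names, matrix=mat)
    sp.inverse()  # assert invertibility now
    return sp


def compensate(t: EventTable, s: SpilloverMatrix) -> EventTable:
    """Replace raw fluorescence columns by their compensated values.

    Scatter and Time are untouched; negative compensated values are kept
    (the logicle scale handles them).
    """
    idx = []
    for nm in s.channel_names:
        if t.scale.get(nm) != "raw":
            raise ValueError(f"channel {nm} is not on the raw scale")
        idx.append(t.channel_names.index(nm))
    inv = s.inverse()
    out = t.copy()
    out.events[:, idx] = t.events[:, idx] @ inv
    for nm in s.channel_names:
        out.scale[nm] = "compensated"
    return out
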