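"""Flow-rate anomaly removal using the Time parameter.

Bubbles and partial clogs during acquisition show up as spikes or dropouts
in the event rate.  Events are binned by acquisition time; bins whose event
count deviates from the median count by more than ``k`` median absolute
deviations are masked out.  Detection is on event rate only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .fcs import EventTable

__all__ = ["FlowCleanReport", "clean_flow_rate", "UnstableAcquisitionError"]


class UnstableAcquisitionError(RuntimeError):
    """Every time bin was flagged: the acquisition is unusable."""


@dataclass
class FlowCleanReport:
    bins_total: int
    bins_removed: int
    events_removed: int
    removed_intervals: List[Tuple[float, float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "bins_total": self.bins_total,
            "bins_removed": self.bins_removed,
            "events_removed": self.events_removed,
            "removed_intervals": [list(iv) for iv in self.removed_intervals],
        }


def clean_flow_rate(t: EventTable, bin_count: int = 100, k: float = 5.0,
                    bin_edges: Optional[np.ndarray] = None
                    ) -> Tuple[np.ndarray, FlowCleanReport]:
    """Mask out events in time bins with anomalous event rate.

    Returns ``(mask, report)`` with ``mask`` True for kept events.  Bin
    boundaries are equal-width over the acquisition span (so the mask is
    invariant to affine rescaling of Time); explicit ``bin_edges`` allow
    idempotent re-runs on a cleaned subset.
    """
    if bin_count < 1 or k <= 0:
        raise ValueError("bin_count and k must be positive")
    time = t.get("TIME")
    if time.size == 0:
        raise ValueError("empty tube")
    tmin, tmax = float(time.min()), float(time.max())
    if tmax <= tmin:
        raise ValueError("Time span must be positive")
    if bin_edges is None:
        bin_edges = np.linspace(tmin, tmax, bin_count + 1)
    else:
        bin_edges = np.asarray(bin_edges, dtype=float)
        bin_count = len(bin_edges) - 1
    which = np.clip(np.searchsorted(bin_edges, time, side="right") - 1,
                    0, bin_count - 1)
    counts = np.bincount(which, minlength=bin_count).astype(float)

    med = np.median(counts)
    mad = np.median(np.abs(counts - med))
    scale = max(mad, 1.0)  # degenerate-MAD guard
    bad_bins = np.abs(counts - med) > k * scale
    if bad_bins.all():
        raise UnstableAcquisitionError("sample unusable -- unstable acquisition")

    mask = ~bad_bins[which]
    intervals: List[Tuple[float, float]] = []
    i = 0
    while i < bin_count:
        if bad_bins[i]:
            j = i
            while j + 1 < bin_count and bad_bins[j + 1]:
                j += 1
            intervals.append((float(bin_edges[i]), float(bin_edges[j + 1])))
            i = j + 1
        else:
            i += 1
    report = FlowCleanReport(
        bins_total=bin_count,
        bins_removed=int(bad_bins.sum()),
        events_removed=int((~mask).sum()),
        removed_intervals=intervals,
    )
    return mask, report
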