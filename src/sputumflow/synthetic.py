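"""Synthetic multi-tube sputum samples and cohorts with ground truth.

Every pipeline stage is testable offline against planted truth: each event
carries a population label (bead, debris, dead, leukocyte subsets, lung
macrophages, TCPP-bright, doublet, artifact populations), and each sample
records the spillover matrix actually applied, so compensation, gating
recall and feature extraction can all be checked against what was planted.

Scatter populations are lognormal on the raw scale; fluorescence is normal
on the logicle display scale and converted to raw signal through the
inverse transform before spillover mixing.  Pulse geometry follows the
singlet ridge: height and width are proportional to area for single cells,
while doublets sum two singlet areas and share their width, placing them
off the ridge where the singlets gate must reject them.

Class-conditional defaults emulate the study's predictor directions: cancer
samples carry more TCPP-bright events per 10K viable singlets, more
intermediate-viability (FVS510 density region 2) events, more
CD206-low/lineage-mid leukocytes, and an older age distribution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .channels import ChannelMap, channel_map, detector_names
from .fcs import RAW_FULL_SCALE, EventTable, write_fcs
from .features import FEATURE_COLUMNS
from .transforms import LogicleParams, SpilloverMatrix, inverse_logicle

__all__ = [
    "PopulationSpec",
    "CohortSpec",
    "SyntheticSample",
    "default_populations",
    "default_spillover",
    "generate_sample",
    "write_sample",
    "generate_cohort",
    "CLASS_TARGETS",
]

#: class-conditional per-10K feature targets (study predictor directions)
CLASS_TARGETS = {
    "non-cancer": {"tcpp_r3": 150, "fvs_r2": 800, "cd206low_linmid": 700},
    "cancer": {"tcpp_r3": 400, "fvs_r2": 1500, "cd206low_linmid": 1200},
}

#: age distributions per class, years (mean, sd)
CLASS_AGES = {"non-cancer": (65.0, 5.5), "cancer": (72.0, 6.0)}

TUBE_KINDS = ("beads", "unstained", "isotype", "blood", "epithelial")


@dataclass
class PopulationSpec:
    """One planted event population of a tube.

    ``channels`` maps a role to a sampler spec tuple:
      ("lognormal", median, sigma)      raw-scale scatter
      ("normal", mean, sd)              raw-scale override (e.g. corner FSC-H)
      ("uniform", lo, hi)               raw-scale noise
      ("logicle_normal", mean, sd)      fluorescence on the display scale
      ("ratio_normal", scatter_role, mean_r, sd_r)
                                        fluorescence targeting a density ratio
                                        r = logicle / log10(raw scatter)
    """

    name: str
    fraction: float
    channels: Dict[str, tuple]
    viability: str = "live"      # live | dead | debris | artifact | bead
    singlet: bool = True

    def __post_init__(self) -> None:
        if self.fraction < 0:
            raise ValueError("population fractions must be non-negative")


@dataclass
class CohortSpec:
    """Synthetic cohort parameters."""

    n_samples: int = 150
    cancer_fraction: float = 28 / 150
    targets: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in CLASS_TARGETS.items()})
    ages: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(CLASS_AGES))
    heterogeneity_sd: float = 0.85   # between-sample logit-scale spread
    #: attenuation of the cancer fvs_r2 shift per decade of age above 65;
    #: induces the model's negative age x FVS-density interaction
    age_fvs_interaction: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.cancer_fraction < 1.0:
            raise ValueError("cancer_fraction must be in (0, 1)")
        n_cancer = int(round(self.n_samples * self.cancer_fraction))
        if n_cancer < 1 or n_cancer >= self.n_samples:
            raise ValueError("infeasible class counts")


@dataclass
class SyntheticSample:
    tubes: Dict[str, EventTable]
    truth: Dict[str, np.ndarray]     # tube -> per-event population label
    spillover: SpilloverMatrix
    status: str
    age: float
    seed: int
    meta: Dict[str, object] = field(default_factory=dict)

    def truth_mask(self, tube: str, *names: str) -> np.ndarray:
        return np.isin(self.truth[tube], names)


# ---------------------------------------------------------------------------
# default population design

_BASELINE = ("logicle_normal", 0.4, 0.2)


def default_populations(status: str = "non-cancer",
                        targets: Optional[Dict[str, float]] = None,
                        tube: str = "blood",
                        corner_fraction: float = 0.0,
                        ssc_contaminant_fraction: float = 0.0,
                        intermediate_viability_fraction: float = 0.0,
                        ) -> List[PopulationSpec]:
    """Build the default planted populations of an assay tube.

    ``targets`` are per-10K counts among viable singlets for tcpp_r3,
    fvs_r2 and cd206low_linmid; they are converted to event fractions so
    the extracted features match them up to gating noise.
    """
    t = dict(CLASS_TARGETS[status])
    if targets:
        t.update(targets)
    marker_x = "CD206" if tube == "blood" else "EPCAM"
    marker_y = "LINEAGE" if tube == "blood" else "PANCK"

    extra = corner_fraction + ssc_contaminant_fraction + intermediate_viability_fraction
    debris_frac, dead_frac = 0.10, 0.12
    live_total = 1.0 - debris_frac - dead_frac - extra
    if live_total <= 0.3:
        raise ValueError("planted special populations leave too few live events")

    frac_tcpp = t["tcpp_r3"] / 1e4 * live_total
    frac_fvs = t["fvs_r2"] / 1e4 * live_total
    frac_linmid = t["cd206low_linmid"] / 1e4 * live_total
    frac_macro = 0.06 * live_total
    frac_bulk = live_total - frac_tcpp - frac_fvs - frac_linmid - frac_macro
    if frac_bulk <= 0:
        raise ValueError("feature targets exceed the live-event budget")

    leuko_scatter = {"FSC-A": ("lognormal", 5.5e4, 0.25),
                     "SSC-A": ("lognormal", 2.0e4, 0.30)}
    common = {"CD45": ("logicle_normal", 3.0, 0.2),
              "FVS510": ("logicle_normal", 0.8, 0.18),
              "TCPP": ("logicle_normal", 1.0, 0.2),
              marker_y: ("logicle_normal", 3.3, 0.15),
              marker_x: ("logicle_normal", 0.8, 0.15)}

    pops = [
        PopulationSpec("debris", debris_frac, {
            "FSC-A": ("lognormal", 1.0e4, 0.35),
            "SSC-A": ("lognormal", 5.0e3, 0.40),
            **{r: _BASELINE for r in ("CD45", "FVS510", "TCPP", marker_x, marker_y)},
        }, viability="debris"),
        PopulationSpec("dead", dead_frac, {
            "FSC-A": ("lognormal", 4.0e4, 0.30),
            "SSC-A": ("lognormal", 6.0e4, 0.25),
            "FVS510": ("logicle_normal", 3.6, 0.2),
            "CD45": ("logicle_normal", 2.5, 0.3),
            "TCPP": ("logicle_normal", 1.5, 0.3),
            marker_x: ("logicle_normal", 1.0, 0.3),
            marker_y: ("logicle_normal", 2.0, 0.5),
        }, viability="dead"),
        PopulationSpec("leukocyte_bulk", frac_bulk, {**leuko_scatter, **common}),
        PopulationSpec("tcpp_bright", frac_tcpp, {
            **leuko_scatter, **common,
            "TCPP": ("ratio_normal", "SSC-A", 0.75, 0.03),
        }),
        PopulationSpec("fvs_intermediate", frac_fvs, {
            "FSC-A": ("lognormal", 3.2e4, 0.08),
            "SSC-A": ("lognormal", 1.5e4, 0.20),
            **{k: v for k, v in common.items() if k != "FVS510"},
            "FVS510": ("logicle_normal", 1.5, 0.15),
        }),
        PopulationSpec("inflammatory_linmid", frac_linmid, {
            **leuko_scatter, **common,
            marker_x: ("logicle_normal", 0.8, 0.15),
            marker_y: ("logicle_normal", 2.75, 0.07),
        }),
        PopulationSpec("macrophage", frac_macro, {
            "FSC-A": ("lognormal", 9.0e4, 0.20),
            "SSC-A": ("lognormal", 3.5e4, 0.25),
            "CD45": ("logicle_normal", 3.2, 0.2),
            "FVS510": ("logicle_normal", 0.8, 0.2),
            "TCPP": ("logicle_normal", 1.2, 0.2),
            marker_x: ("logicle_normal", 3.25, 0.12),
            marker_y: ("logicle_normal", 1.2, 0.25),
        }),
    ]
    if corner_fraction > 0:
        pops.append(PopulationSpec("corner_artifact", corner_fraction, {
            "FSC-A": ("lognormal", 1.2e5, 0.15),
            "SSC-A": ("lognormal", 2.0e3, 0.30),
            "FSC-H": ("normal", 2.1e5, 8e3),
            "SSC-H": ("normal", 150.0, 40.0),
            **{r: _BASELINE for r in ("CD45", "FVS510", "TCPP", marker_x, marker_y)},
        }, viability="artifact"))
    if ssc_contaminant_fraction > 0:
        pops.append(PopulationSpec("ssc_contaminant", ssc_contaminant_fraction, {
            "FSC-A": ("lognormal", 2.2e5, 0.05),
            "SSC-A": ("lognormal", 8.0e4, 0.10),
            "FSC-W": ("normal", 2.0e3, 5e2),
            "FVS510": ("logicle_normal", 1.2, 0.2),
            **{r: _BASELINE for r in ("CD45", "TCPP", marker_x, marker_y)},
        }, viability="artifact"))
    if intermediate_viability_fraction > 0:
        # broad live + just-below-threshold population with high SSC-A,
        # recreating the viability-reset scenario
        pops.append(PopulationSpec("intermediate_viability",
                                   intermediate_viability_fraction, {
            "FSC-A": ("lognormal", 5.0e4, 0.20),
            "SSC-A": ("lognormal", 6.5e4, 0.10),
            # pulse height stays leukocyte-like so the population slips into
            # the core gate and drags the tail threshold past it, setting up
            # the viability-reset heuristic
            "SSC-H": ("normal", 1.8e4, 2.0e3),
            **{k: v for k, v in common.items() if k != "FVS510"},
            "FVS510": ("logicle_normal", 2.9, 0.25),
        }, viability="artifact"))
        for p in pops:
            if p.viability == "live":
                p.channels["FVS510"] = ("logicle_normal", 1.3, 0.45)
            if p.name == "dead":
                p.channels["FVS510"] = ("logicle_normal", 4.2, 0.15)
    total = sum(p.fraction for p in pops)
    return [replace(p, fraction=p.fraction / total) for p in pops]


def default_spillover(dialect: str = "lsrii") -> SpilloverMatrix:
    """Default non-trivial spillover over the five fluorescence detectors."""
    names = detector_names(dialect)
    mat = np.eye(5)
    mat[0, 1] = 0.12   # FITC-like -> PE-like
    mat[1, 2] = 0.08
    mat[2, 4] = 0.06
    mat[3, 0] = 0.05
    return SpilloverMatrix(channel_names=names, matrix=mat)


# ---------------------------------------------------------------------------
# event synthesis

def _sample_channel(spec: tuple, n: int, rng: np.random.Generator,
                    scatter: Dict[str, np.ndarray],
                    lp: LogicleParams) -> np.ndarray:
    kind = spec[0]
    if kind == "lognormal":
        _, median, sigma = spec
        return rng.lognormal(np.log(median), sigma, size=n)
    if kind == "normal":
        _, mean, sd = spec
        return rng.normal(mean, sd, size=n)
    if kind == "uniform":
        _, lo, hi = spec
        return rng.uniform(lo, hi, size=n)
    if kind == "logicle_normal":
        _, mean, sd = spec
        return inverse_logicle(rng.normal(mean, sd, size=n), lp)
    if kind == "ratio_normal":
        _, scatter_role, mean_r, sd_r = spec
        r = rng.normal(mean_r, sd_r, size=n)
        return inverse_logicle(r * np.log10(np.maximum(scatter[scatter_role], 2.0)), lp)
    raise ValueError(f"unknown sampler kind {kind!r}")


def _assay_tube(pops: Sequence[PopulationSpec], n_events: int,
                rng: np.random.Generator, cmap: ChannelMap,
                spill: SpilloverMatrix, lp: LogicleParams,
                doublet_fraction: float = 0.06,
                duration: float = 300.0,
                anomaly: Optional[tuple] = None
                ) -> Tuple[EventTable, np.ndarray]:
    fracs = np.array([p.fraction for p in pops])
    if abs(fracs.sum() - 1.0) > 1e-6:
        raise ValueError("population fractions must sum to 1")
    counts = rng.multinomial(n_events, fracs)
    fluor_roles = [r for r in cmap.roles
                   if r not in ("FSC-A", "FSC-H", "FSC-W", "SSC-A", "SSC-H", "TIME")]

    rows: List[np.ndarray] = []
    labels: List[np.ndarray] = []
    col_roles = ["FSC-A", "FSC-H", "FSC-W", "SSC-A", "SSC-H"] + fluor_roles
    for p, n in zip(pops, counts):
        if n == 0:
            continue
        scatter: Dict[str, np.ndarray] = {}
        for role in ("FSC-A", "SSC-A"):
            scatter[role] = _sample_channel(p.channels[role], n, rng, scatter, lp)
        fsc_a, ssc_a = scatter["FSC-A"], scatter["SSC-A"]
        fsc_h = fsc_a * 0.95 * (1.0 + rng.normal(0, 0.02, n))
        fsc_w = fsc_a * (0.95 + rng.normal(0, 0.03, n))
        ssc_h = ssc_a * 0.90 * (1.0 + rng.normal(0, 0.05, n))
        if "FSC-H" in p.channels:
            fsc_h = _sample_channel(p.channels["FSC-H"], n, rng, scatter, lp)
        if "FSC-W" in p.channels:
            fsc_w = _sample_channel(p.channels["FSC-W"], n, rng, scatter, lp)
        if "SSC-H" in p.channels:
            ssc_h = _sample_channel(p.channels["SSC-H"], n, rng, scatter, lp)
        block = [fsc_a, fsc_h, fsc_w, ssc_a, ssc_h]
        for role in fluor_roles:
            spec = p.channels.get(role, _BASELINE)  # unspecified -> autofluorescence
            block.append(_sample_channel(spec, n, rng, scatter, lp))
        rows.append(np.column_stack(block))
        labels.append(np.full(n, p.name, dtype=object))

    events = np.vstack(rows)
    labels = np.concatenate(labels)

    # doublets: pairs of live singlet draws; areas sum, width is shared
    live_rows = np.flatnonzero(np.isin(
        labels, [p.name for p in pops if p.viability == "live"]))
    n_doublets = int(doublet_fraction * live_rows.size / 2)
    if n_doublets > 0:
        a = rng.choice(live_rows, size=n_doublets, replace=False)
        remaining = np.setdiff1d(live_rows, a, assume_unique=False)
        b = rng.choice(remaining, size=n_doublets, replace=False)
        area_cols = [0, 3] + list(range(5, 5 + len(fluor_roles)))
        merged = events[a].copy()
        merged[:, area_cols] = events[a][:, area_cols] + events[b][:, area_cols]
        merged[:, 1] = np.maximum(events[a][:, 1], events[b][:, 1])   # FSC-H
        merged[:, 4] = np.maximum(events[a][:, 4], events[b][:, 4])   # SSC-H
        merged[:, 2] = 0.5 * (events[a][:, 2] + events[b][:, 2])      # FSC-W
        events[a] = merged
        labels[a] = "doublet"
        keep = np.ones(len(events), dtype=bool)
        keep[b] = False
        events, labels = events[keep], labels[keep]

    # spillover mixing of the fluorescence block (true -> observed)
    fl = events[:, 5:5 + len(fluor_roles)]
    det_of_role = [cmap.resolve(r) for r in fluor_roles]
    order = [spill.channel_names.index(d) for d in det_of_role]
    s_sub = spill.matrix[np.ix_(order, order)]
    events[:, 5:5 + len(fluor_roles)] = fl @ s_sub

    np.clip(events, 0.0, RAW_FULL_SCALE, out=events)

    # interleave populations in time
    perm = rng.permutation(len(events))
    events, labels = events[perm], labels[perm]
    time = np.sort(rng.uniform(0.0, duration, size=len(events)))
    if anomaly is not None:
        time = _apply_time_anomaly(time, anomaly, duration, rng)
    events = np.column_stack([events, time])

    names = [cmap.resolve(r) for r in col_roles] + [cmap.resolve("TIME")]
    table = EventTable(events=events, channel_names=names, channel_map=cmap)
    return table, labels


def _apply_time_anomaly(time: np.ndarray, anomaly: tuple, duration: float,
                        rng: np.random.Generator) -> np.ndarray:
    kind = anomaly[0]
    if kind == "spike":
        # squeeze a fraction of events into a narrow window (burst)
        _, center, width, frac = anomaly
        n = int(frac * time.size)
        idx = rng.choice(time.size, size=n, replace=False)
        time = time.copy()
        time[idx] = rng.uniform(center - width / 2, center + width / 2, size=n)
        return np.sort(time)
    if kind == "gap":
        _, start, stop = anomaly
        time = time.copy()
        inside = (time >= start) & (time < stop)
        # clog: no events arrive during the gap
        time[inside] = stop + (time[inside] - start) * 1e-3
        return np.sort(time)
    raise ValueError(f"unknown anomaly kind {kind!r}")


def _simple_tube(events: np.ndarray, labels: np.ndarray, cmap: ChannelMap,
                 rng: np.random.Generator, duration: float = 60.0
                 ) -> Tuple[EventTable, np.ndarray]:
    perm = rng.permutation(len(events))
    events, labels = events[perm], labels[perm]
    time = np.sort(rng.uniform(0.0, duration, size=len(events)))
    events = np.column_stack([events, time])
    names = [cmap.resolve(r) for r in
             ("FSC-A", "FSC-H", "FSC-W", "SSC-A", "SSC-H",
              "LINEAGE", "CD45", "CD206", "FVS510", "TCPP")] + [cmap.resolve("TIME")]
    # columns already ordered as detector slots; see _control_matrix
    table = EventTable(events=np.clip(events, 0.0, RAW_FULL_SCALE),
                       channel_names=names, channel_map=cmap)
    return table, labels


def _control_matrix(n: int, rng: np.random.Generator, lp: LogicleParams,
                    positive_detector: Optional[int] = None,
                    spill: Optional[SpilloverMatrix] = None) -> np.ndarray:
    """Scatter + 5-detector raw matrix for control tubes (beads excluded)."""
    fsc = rng.lognormal(np.log(5.0e4), 0.25, n)
    ssc = rng.lognormal(np.log(2.0e4), 0.30, n)
    fsc_h = fsc * 0.95 * (1 + rng.normal(0, 0.02, n))
    fsc_w = fsc * (0.95 + rng.normal(0, 0.03, n))
    ssc_h = ssc * 0.90 * (1 + rng.normal(0, 0.05, n))
    fl = inverse_logicle(rng.normal(0.4, 0.2, size=(n, 5)), lp)
    if positive_detector is not None:
        pos = rng.random(n) < 0.5
        fl[pos, positive_detector] = inverse_logicle(
            rng.normal(3.5, 0.15, size=int(pos.sum())), lp)
    if spill is not None:
        fl = fl @ spill.matrix
    return np.column_stack([fsc, fsc_h, fsc_w, ssc, ssc_h, fl])


def generate_sample(status: str = "non-cancer", n_events: int = 50_000,
                    seed: int = 0, targets: Optional[Dict[str, float]] = None,
                    dialect: str = "lsrii",
                    spillover: Optional[SpilloverMatrix] = None,
                    logicle_params: LogicleParams = LogicleParams(),
                    age: Optional[float] = None,
                    doublet_fraction: float = 0.06,
                    corner_fraction: float = 0.0,
                    ssc_contaminant_fraction: float = 0.0,
                    intermediate_viability_fraction: float = 0.0,
                    anomaly: Optional[tuple] = None,
                    n_bead_events: int = 5_000,
                    n_control_events: int = 5_000,
                    populations: Optional[List[PopulationSpec]] = None
                    ) -> SyntheticSample:
    """Generate the full tube set of one synthetic sputum sample.

    Returns FCS-writable tubes (beads, per-detector compensation controls,
    unstained, isotype, blood, epithelial) with per-event truth labels.
    Identical seeds give byte-identical event matrices.
    """
    if status not in CLASS_TARGETS:
        raise ValueError(f"unknown status {status!r}")
    rng = np.random.default_rng(seed)
    spill = spillover or default_spillover(dialect)
    lp = logicle_params
    if age is None:
        mu, sd = CLASS_AGES[status]
        age = float(np.clip(rng.normal(mu, sd), 45.0, 90.0))

    tubes: Dict[str, EventTable] = {}
    truth: Dict[str, np.ndarray] = {}

    # beads: dominant 5 um cluster + uniform noise
    cmap_ctrl = channel_map(dialect, tube="control")
    n_noise = int(0.1 * n_bead_events)
    n_clust = n_bead_events - n_noise
    bead_fsc = rng.normal(3.0e4, 2.0e3, n_clust)
    bead_ssc = rng.normal(1.5e4, 1.5e3, n_clust)
    noise = rng.uniform(0, RAW_FULL_SCALE, size=(n_noise, 2))
    fsc = np.concatenate([bead_fsc, noise[:, 0]])
    ssc = np.concatenate([bead_ssc, noise[:, 1]])
    fl = inverse_logicle(rng.normal(0.4, 0.2, size=(fsc.size, 5)), lp)
    bead_events = np.column_stack([
        fsc, fsc * 0.95, fsc * 0.97, ssc, ssc * 0.9, fl])
    bead_labels = np.array(["bead"] * n_clust + ["noise"] * n_noise, dtype=object)
    tubes["beads"], truth["beads"] = _simple_tube(bead_events, bead_labels,
                                                  cmap_ctrl, rng)

    # unstained / isotype
    for name in ("unstained", "isotype"):
        ev = _control_matrix(n_control_events, rng, lp)
        tubes[name], truth[name] = _simple_tube(
            ev, np.full(n_control_events, "unstained", dtype=object), cmap_ctrl, rng)

    # one single-stain compensation tube per detector
    for k, det in enumerate(detector_names(dialect)):
        ev = _control_matrix(n_control_events, rng, lp,
                             positive_detector=k, spill=spill)
        tubes[f"comp_{det}"], truth[f"comp_{det}"] = _simple_tube(
            ev, np.full(n_control_events, f"comp_{det}", dtype=object),
            cmap_ctrl, rng)

    # assay tubes
    for tube in ("blood", "epithelial"):
        cmap = channel_map(dialect, tube=tube)
        pops = populations if populations is not None else default_populations(
            status, targets, tube=tube,
            corner_fraction=corner_fraction,
            ssc_contaminant_fraction=ssc_contaminant_fraction,
            intermediate_viability_fraction=intermediate_viability_fraction)
        tubes[tube], truth[tube] = _assay_tube(
            pops, n_events, rng, cmap, spill, lp,
            doublet_fraction=doublet_fraction, anomaly=anomaly)

    return SyntheticSample(tubes=tubes, truth=truth, spillover=spill,
                           status=status, age=age, seed=seed,
                           meta={"n_events": n_events, "dialect": dialect})


def write_sample(sample: SyntheticSample, directory) -> Dict[str, str]:
    """Write FCS files plus sidecar truth CSVs and metadata JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, str] = {}
    for name, tube in sample.tubes.items():
        p = directory / f"{name}.fcs"
        write_fcs(p, tube.events, tube.channel_names)
        pd.DataFrame({"event": np.arange(len(sample.truth[name])),
                      "population": sample.truth[name]}
                     ).to_csv(directory / f"{name}.truth.csv", index=False)
        paths[name] = str(p)
    (directory / "sample.json").write_text(json.dumps({
        "status": sample.status, "age": sample.age, "seed": sample.seed,
        "meta": sample.meta}, indent=2))
    sample.spillover.to_csv(directory / "spillover.truth.csv")
    return paths


# ---------------------------------------------------------------------------
# cohorts

def _logit(p: float) -> float:
    return float(np.log(p / (1 - p)))


def generate_cohort(spec: CohortSpec, mode: str = "features",
                    n_events: int = 20_000):
    """Generate a labelled cohort.

    ``features`` mode draws the per-10K feature counts directly from the
    class-conditional targets with between-sample logit-normal
    heterogeneity and binomial counting noise: fast, used for classifier
    work.  ``fcs`` mode generates full tube sets per sample (with
    per-sample feature fractions drawn the same way) for end-to-end runs.

    Returns ``(frame, labels)`` in features mode, where ``frame`` holds the
    feature columns; in fcs mode returns ``(samples, labels)`` with a list
    of :class:`SyntheticSample`.
    """
    rng = np.random.default_rng(spec.seed)
    n_cancer = int(round(spec.n_samples * spec.cancer_fraction))
    labels = np.array([1] * n_cancer + [0] * (spec.n_samples - n_cancer))
    rng.shuffle(labels)

    def draw_targets(status: str, age: float) -> Dict[str, float]:
        out = {}
        for feat in spec.targets[status]:
            base = _logit(np.clip(spec.targets["non-cancer"][feat] / 1e4,
                                  1e-4, 0.5))
            shift = _logit(np.clip(spec.targets[status][feat] / 1e4,
                                   1e-4, 0.5)) - base
            if feat == "fvs_r2" and status == "cancer":
                # the FVS-density signal fades with age in cancer samples,
                # which the classifier must absorb as a negative age x fvs term
                shift *= max(0.0, 1.0 - spec.age_fvs_interaction
                             * (age - 65.0) / 10.0)
            lp = base + shift + rng.normal(0.0, spec.heterogeneity_sd)
            out[feat] = 1.0 / (1.0 + np.exp(-lp))
        return out

    if mode == "features":
        rows = []
        for lab in labels:
            status = "cancer" if lab == 1 else "non-cancer"
            mu, sd = spec.ages[status]
            age = float(np.clip(rng.normal(mu, sd), 45, 90))
            probs = draw_targets(status, age)
            singlets = int(rng.integers(25_000, 40_000))
            rows.append({
                "age": age,
                "tcpp_r3_per10k": int(rng.binomial(10_000, probs["tcpp_r3"])),
                "fvs_r2_per10k": int(rng.binomial(10_000, probs["fvs_r2"])),
                "cd206low_linmid_per10k": int(rng.binomial(
                    10_000, probs["cd206low_linmid"])),
                "macrophages": int(rng.poisson(0.06 * singlets)),
                "viable_singlets": singlets,
                "eligible": True,
            })
        return pd.DataFrame(rows, columns=FEATURE_COLUMNS), labels

    if mode == "fcs":
        samples = []
        for i, lab in enumerate(labels):
            status = "cancer" if lab == 1 else "non-cancer"
            mu, sd = spec.ages[status]
            age = float(np.clip(rng.normal(mu, sd), 45, 90))
            probs = draw_targets(status, age)
            targets = {k: v * 1e4 for k, v in probs.items()}
            sub_seed = int(rng.integers(0, 2**31 - 1))
            samples.append(generate_sample(status=status, n_events=n_events,
                                           seed=sub_seed, targets=targets,
                                           age=age))
        return samples, labels

    raise ValueError(f"unknown cohort mode {mode!r}")
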