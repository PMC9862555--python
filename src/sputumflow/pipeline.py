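"""End-to-end per-sample and per-cohort orchestration.

The per-sample flow mirrors the deployed assay pipeline: file QC ->
flow-rate cleaning -> de-novo spillover -> logicle -> gating -> eligibility
(>= 10,000 viable singlets, >= 10 lung-macrophage events) -> features ->
probability -> call.  Each QC decision point can short-circuit the run with
a structured failure naming its stage; no code path yields a cancer call
for a QC-failed sample.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from . import __version__
from .channels import ChannelMap, channel_map, detector_names
from .classifier import (LungFlowClassifier, ModelCoefficients, classify,
                         fit_logistic, predict_probability, choose_cutoff)
from .dxmetrics import diagnostic_report, report_to_frame
from .fcs import EventTable, FcsReadError, read_fcs
from .features import FEATURE_COLUMNS, extract_features
from .flow_qc import clean_flow_rate, UnstableAcquisitionError
from .gating import GateConfig, GatingError, run_gating
from .synthetic import SyntheticSample
from .transforms import (LogicleParams, SpilloverMatrix, compensate,
                         derive_spillover, logicle_table,
                         UninformativeControlError)

__all__ = ["SampleReport", "QcFailure", "run_sample", "run_cohort",
           "PipelineConfig"]

SCHEMA = "sputumflow.report/1"


class QcFailure(RuntimeError):
    """Structured QC short-circuit; names the pipeline decision point."""

    def __init__(self, stage: str, message: str):
        super().__init__(message)
        self.stage = stage


@dataclass
class PipelineConfig:
    gate: GateConfig = field(default_factory=GateConfig)
    logicle: LogicleParams = field(default_factory=LogicleParams)
    flowclean_bin_count: int = 100
    flowclean_k: float = 5.0
    assay_tube: str = "blood"
    dialect: str = "lsrii"
    cutoff: float = 0.28


@dataclass
class SampleReport:
    sample_id: str
    qc: Dict[str, object] = field(default_factory=dict)
    gating: Optional[dict] = None
    features: Optional[dict] = None
    eligibility: Optional[dict] = None
    probability: Optional[float] = None
    cutoff: Optional[float] = None
    call: Optional[str] = None
    failure: Optional[dict] = None
    heuristics: List[str] = field(default_factory=list)
    seed: int = 0
    version: str = __version__
    schema: str = SCHEMA

    def to_dict(self) -> dict:
        return {
            "schema": self.schema, "version": self.version,
            "sample_id": self.sample_id, "qc": self.qc, "gating": self.gating,
            "features": self.features, "eligibility": self.eligibility,
            "probability": self.probability, "cutoff": self.cutoff,
            "call": self.call, "failure": self.failure,
            "heuristics": self.heuristics, "seed": self.seed,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, path) -> "SampleReport":
        doc = json.loads(Path(path).read_text())
        if doc.pop("schema") != SCHEMA:
            raise ValueError("unknown report schema")
        doc["version"] = doc.pop("version")
        return cls(**doc)


def _load_tube(src, cmap: ChannelMap, required: Sequence[str]) -> EventTable:
    if isinstance(src, EventTable):
        src.validate(required)
        return src.copy()
    return read_fcs(src, cmap, required_roles=required)


def run_sample(tubes: Dict[str, Union[str, Path, EventTable]], age: float,
               model: ModelCoefficients,
               config: PipelineConfig = PipelineConfig(),
               sample_id: str = "sample") -> SampleReport:
    """Execute the full assay pipeline on one sample's tube set.

    ``tubes`` maps tube names (``beads``, ``unstained``, ``blood``,
    ``epithelial``, ``comp_<detector>``) to FCS paths or in-memory tables.
    """
    report = SampleReport(sample_id=sample_id, seed=config.gate.seed)
    assay = config.assay_tube
    cmap_assay = channel_map(config.dialect, tube=assay)
    cmap_ctrl = channel_map(config.dialect, tube="control")
    scatter_roles = ["FSC-A", "FSC-H", "FSC-W", "SSC-A", "SSC-H", "TIME"]
    try:
        # --- file QC diamond -------------------------------------------
        try:
            beads = _load_tube(tubes["beads"], cmap_ctrl, scatter_roles)
            unstained = _load_tube(tubes["unstained"], cmap_ctrl, scatter_roles)
            t = _load_tube(tubes[assay], cmap_assay,
                           scatter_roles + list(cmap_assay.fluor_roles()))
            controls = {}
            for det in detector_names(config.dialect):
                key = f"comp_{det}"
                if key in tubes:
                    controls[det] = _load_tube(tubes[key], cmap_ctrl, ["TIME"])
        except (FcsReadError, KeyError) as exc:
            raise QcFailure("file_qc", f"file QC failure: {exc}") from exc
        report.qc["file_qc"] = "pass"

        # --- flow-rate QC diamond --------------------------------------
        try:
            mask, clean = clean_flow_rate(t, config.flowclean_bin_count,
                                          config.flowclean_k)
        except UnstableAcquisitionError as exc:
            raise QcFailure("flow_rate_qc", str(exc)) from exc
        report.qc["flow_rate_qc"] = clean.to_dict()
        t = EventTable(events=t.events[mask], channel_names=t.channel_names,
                       channel_map=t.channel_map, scale=dict(t.scale))

        # --- compensation and logicle ----------------------------------
        fluor_dets = [d for d in detector_names(config.dialect) if d in controls]
        if len(fluor_dets) == len(detector_names(config.dialect)):
            try:
                spill = derive_spillover({d: controls[d] for d in fluor_dets},
                                         unstained, seed=config.gate.seed)
            except UninformativeControlError as exc:
                raise QcFailure("compensation", str(exc)) from exc
            t = compensate(t, spill)
            report.qc["compensation"] = "de novo"
        else:
            report.qc["compensation"] = "skipped (no control tubes)"
        t = logicle_table(t, cmap_assay.fluor_roles(), default=config.logicle)

        # --- gating -----------------------------------------------------
        try:
            g = run_gating({"beads": beads, assay: t}, config.gate, assay=assay)
        except GatingError as exc:
            raise QcFailure(exc.stage, str(exc)) from exc
        report.gating = {k: int(v) for k, v in g.counts.items()}
        report.gating["viability_threshold"] = g.viability_threshold
        report.gating["fsc_min"] = g.fsc_min
        report.heuristics = list(g.heuristics_applied)

        # --- eligibility diamond ---------------------------------------
        fv, elig = extract_features(g, t, age)
        report.features = fv.to_row(elig.eligible)
        report.eligibility = {"enough_singlets": elig.enough_singlets,
                              "lung_confirmed": elig.lung_confirmed,
                              "eligible": elig.eligible}
        if not elig.eligible:
            reason = []
            if not elig.enough_singlets:
                reason.append(f"{fv.viable_singlets} < 10,000 viable singlets")
            if not elig.lung_confirmed:
                reason.append(f"{fv.macrophage_count} < 10 lung macrophages")
            raise QcFailure("eligibility", "; ".join(reason))
        report.qc["eligibility"] = "pass"

        # --- model ------------------------------------------------------
        p = predict_probability(model, fv, eligible=True)
        report.probability = p
        report.cutoff = config.cutoff
        report.call = classify(p, config.cutoff)
    except QcFailure as exc:
        report.failure = {"stage": exc.stage, "message": str(exc)}
    return report


# ---------------------------------------------------------------------------
# cohort-level runs


def _cohort_features(samples, ages, config: PipelineConfig) -> pd.DataFrame:
    rows = []
    for i, s in enumerate(samples):
        if isinstance(s, SyntheticSample):
            tubes = dict(s.tubes)
            age = s.age if ages is None else ages[i]
            sid = f"syn{i:04d}"
        else:
            tubes, age, sid = s["tubes"], s["age"], s.get("sample_id", f"s{i:04d}")
        rep = run_sample(tubes, age, _NULL_MODEL, config, sample_id=sid)
        row = dict(rep.features or {c: np.nan for c in FEATURE_COLUMNS})
        row["sample_id"] = sid
        row["qc_failed"] = rep.failure is not None and \
            rep.failure["stage"] != "eligibility"
        rows.append(row)
    return pd.DataFrame(rows)


_NULL_MODEL = ModelCoefficients(values={n: 0.0 for n in
                                        ("b0", "b1", "b2", "b3", "b4", "b5")})


def run_cohort(samples: Sequence, labels=None, ages=None, mode: str = "predict",
               model: Optional[ModelCoefficients] = None,
               config: PipelineConfig = PipelineConfig(),
               n_boot: int = 500, seed: int = 0) -> dict:
    """Run the pipeline over a cohort of samples.

    ``samples`` is a sequence of :class:`SyntheticSample` or dicts with
    ``tubes``/``age`` entries.  ``train`` fits the model and picks a
    ROC-based cutoff; ``predict`` scores with a given model; ``evaluate``
    additionally assembles the diagnostic-accuracy report when labels are
    present.
    """
    feats = _cohort_features(samples, ages, config)
    usable = feats[~feats["qc_failed"] & feats["eligible"].astype(bool)]
    out: dict = {"n_samples": len(feats), "n_usable": len(usable),
                 "features": feats}

    if mode == "train":
        if labels is None:
            raise ValueError("training requires labels")
        y = np.asarray(labels, dtype=float)[usable.index]
        model = fit_logistic(usable, y)
        clf = LungFlowClassifier()
        clf.model_ = model
        probs = clf.predict_proba(usable)[:, 1]
        cutoff, roc, auc_value = choose_cutoff(probs, y.astype(int))
        out.update({"model": model, "cutoff": cutoff, "auc": auc_value,
                    "roc": roc})
        return out

    if model is None:
        raise ValueError("predict/evaluate require a fitted model")
    clf = LungFlowClassifier(cutoff=config.cutoff)
    clf.model_ = model
    probs = clf.predict_proba(usable)[:, 1]
    calls = np.array([classify(p, config.cutoff) for p in probs])
    out["calls"] = pd.DataFrame({"sample_id": usable["sample_id"],
                                 "probability": probs, "call": calls})
    if mode == "evaluate" and labels is not None:
        y = np.asarray(labels, dtype=int)[usable.index]
        rep = diagnostic_report(y, probs, config.cutoff, n_boot=n_boot,
                                seed=seed)
        out["diagnostics"] = rep
        out["diagnostics_table"] = report_to_frame(rep)
    return out
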