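"""End-to-end pipeline: cohort -> features -> adjacency -> CV -> reports.

A :class:`RunConfig` (YAML-serialisable) fixes every knob of a run; its
canonical-JSON hash is embedded in every artifact so two runs with the same
hash are guaranteed to have produced identical metrics.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import SyntheticCohortSpec, generate_cohort
from .connectivity import DEFAULT_THRESHOLD, build_adjacency, pearson_fc
from .features import featurize_cohort
from .gat import ModelConfig
from .io import load_cohort, write_adjacency
from .training import TrainConfig, cross_validate

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("braingat")


@dataclass(frozen=True)
class RunConfig:
    """Everything a full run needs; YAML round-trips losslessly."""

    manifest: str | None = None           # load a real cohort ...
    simulate: SyntheticCohortSpec | None = None   # ... or synthesise one
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    threshold: float = DEFAULT_THRESHOLD
    adjacency_mode: str = "mean"
    transpose: bool = False
    roi_labels: str | None = None         # optional TSV: roi_index_1based -> names
    out_dir: str = "braingat_run"

    def __post_init__(self):
        if (self.manifest is None) == (self.simulate is None):
            raise ValueError("exactly one of manifest/simulate must be set")

    # -- serialisation ----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("simulate") is not None:
            sim = dict(d["simulate"])
            if "planted_rois" in sim:
                sim["planted_rois"] = tuple(sim["planted_rois"])
            d["simulate"] = SyntheticCohortSpec(**sim)
        if d.get("model") is not None:
            d["model"] = ModelConfig(**d["model"])
        if d.get("train") is not None:
            d["train"] = TrainConfig(**d["train"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        """Hash of every field that can influence results (the output
        location is excluded: two runs with equal hashes must agree)."""
        d = self.to_dict()
        d.pop("out_dir")
        canon = json.dumps(d, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write artifacts under ``config.out_dir``.

    Artifacts: cohort TSVs + manifest (simulated runs), long-format feature
    CSV, full-cohort adjacency TSV + sidecar, metrics JSON, ROI-importance
    CSV and a log file.  Returns the metrics dict.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    chash = config.config_hash()
    try:
        log.info("run start: config hash %s, seed %s", chash, config.train.seed)
        config.to_yaml(out / "config.yaml")

        def stage(name):
            log.info("stage %s", name)
            return time.perf_counter()

        t0 = stage("cohort")
        if config.simulate is not None:
            cohort = generate_cohort(config.simulate, out_dir=out / "cohort")
        else:
            cohort = load_cohort(config.manifest, transpose=config.transpose)
        labels = [s.label for s in cohort]
        if any(l is None for l in labels):
            raise ValueError("cohort stage: every subject needs a 0/1 label")
        log.info("cohort: %d subjects (%.2fs)", len(cohort),
                 time.perf_counter() - t0)

        t0 = stage("features")
        features = featurize_cohort(cohort)
        feat_rows = []
        for f in features:
            for r in range(f.n_roi):
                for name, v in zip(f.feature_names, f.values[r]):
                    feat_rows.append((f.subject_id, r + 1, name, v))
        pd.DataFrame(feat_rows, columns=["subject_id", "roi_index_1based",
                                         "feature_name", "value"]).to_csv(
            out / "features.csv", index=False)
        log.info("features: %d x %d x 16 (%.2fs)", len(features),
                 features[0].n_roi, time.perf_counter() - t0)

        t0 = stage("connectivity")
        fcs = [pearson_fc(s) for s in cohort]
        full_adj = build_adjacency(fcs, labels, config.threshold, "mean")
        write_adjacency(full_adj, out / "adjacency.tsv",
                        extra={"config_hash": chash,
                               "note": "whole-cohort adjacency (reference); "
                                       "CV rebuilds per fold from training "
                                       "subjects only"})
        log.info("connectivity: %d edges kept (%.2fs)",
                 int(np.count_nonzero(np.triu(full_adj.values, 1))),
                 time.perf_counter() - t0)

        t0 = stage("cross-validation")
        result = cross_validate(features, fcs, labels, config.model,
                                config.train, config.threshold,
                                config.adjacency_mode)
        metrics = result.metrics_dict()
        metrics["config_hash"] = chash
        (out / "metrics.json").write_text(json.dumps(metrics, indent=2))
        log.info("cv: pooled accuracy %.4f (%.2fs)",
                 result.aggregate.accuracy, time.perf_counter() - t0)

        roi_labels = None
        if config.roi_labels:
            roi_labels = pd.read_csv(config.roi_labels, sep="\t")
        ranked = result.importance.ranked(roi_labels)
        ranked.insert(0, "config_hash", chash)
        ranked.to_csv(out / "importance.csv", index=False)
        log.info("run done")
        return metrics
    except Exception:
        log.exception("pipeline aborted")
        raise
    finally:
        log.removeHandler(fh)
        fh.close()
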