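"""End-to-end pipeline: simulate -> segment -> extract -> train -> evaluate.

A :class:`RunConfig` captures every stage parameter plus one global seed;
the seed is expanded into per-stage substreams so stages can be rerun
independently yet reproducibly.  Every intermediate artifact is persisted
under the output directory and the resolved config is written next to the
outputs, so rerunning an emitted config reproduces identical files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as efio
from .containers import FeatureMatrix, concat_segment_sets
from .evaluate import compare_classifiers, make_classifier
from .features import ARSpec, BandSpec, extract_ar_features, extract_psd_features
from .preprocess import segment_moving_window
from .synthetic import SynthConfig, generate_dataset

log = logging.getLogger("eegfatigue")


@dataclass
class RunConfig:
    """Resolved parameters of one pipeline run."""

    seed: int = 0
    out_dir: str = "run"
    log_level: str = "INFO"
    # simulate
    n_subjects: int = 43
    fs: float = 256.0
    n_channels: int = 32
    duration_s: float = 20.0
    noise_sd: float = 0.5
    # segment
    window_s: float = 2.0
    overlap_s: float = 1.75
    # extract
    method: str = "ar"  # "ar" or "psd"
    ar_order: int = 5
    # train / evaluate
    classifiers: list[str] = field(default_factory=lambda: ["sparse-dbn"])
    hidden: list[int] = field(default_factory=lambda: [15, 15])
    eta: float = 0.01
    lambda_: float = 1.0
    p_target: float = 0.02
    max_epoch: int = 200
    max_fail: int = 10
    protocol: str = "holdout"
    k: int = 3
    split_by_subject: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))


def _stage_seed(seed: int, stage: str) -> int:
    # stable per-stage substream below 2**31
    return int(np.random.SeedSequence([seed, sum(map(ord, stage))]).generate_state(1)[0] % (2**31))


def build_features(cfg: RunConfig) -> tuple[FeatureMatrix, np.ndarray]:
    """Simulate, segment and extract; returns features and subject groups."""
    synth = SynthConfig(
        n_subjects=cfg.n_subjects,
        fs=cfg.fs,
        n_channels=cfg.n_channels,
        duration_s=cfg.duration_s,
        noise_sd=cfg.noise_sd,
        seed=_stage_seed(cfg.seed, "simulate"),
    )
    recordings, _ = generate_dataset(synth)
    seg_sets = [segment_moving_window(r, cfg.window_s, cfg.overlap_s) for r in recordings]
    segs = concat_segment_sets(seg_sets)
    if cfg.method == "ar":
        fm = extract_ar_features(segs, ARSpec(order=cfg.ar_order))
    elif cfg.method == "psd":
        fm = extract_psd_features(segs, BandSpec())
    else:
        raise ValueError(f"unknown feature method {cfg.method!r}; expected 'ar' or 'psd'")
    groups = np.array([p[0] for p in segs.provenance])
    return fm, groups


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute every stage, persisting intermediates; returns the out dir."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=cfg.log_level)
    cfg.to_yaml(out / "config.yaml")

    stage = "simulate+segment+extract"
    try:
        log.info("stage %s", stage)
        fm, groups = build_features(cfg)
        efio.write_features(fm, out / "features.tsv")

        stage = "train+evaluate"
        log.info("stage %s", stage)
        clf_seed = _stage_seed(cfg.seed, "train")
        classifiers = {}
        for kind in cfg.classifiers:
            kw = dict(max_epoch=cfg.max_epoch, max_fail=cfg.max_fail)
            if kind in ("dbn", "sparse-dbn"):
                kw.update(eta=cfg.eta, p_target=cfg.p_target)
                if kind == "sparse-dbn":
                    kw["lambda_"] = cfg.lambda_
                classifiers[kind] = make_classifier(kind, seed=clf_seed, hidden=cfg.hidden, **kw)
            else:
                # the ANN keeps its own learning-rate default (trained from scratch)
                classifiers[kind] = make_classifier(kind, seed=clf_seed,
                                                    hidden=cfg.hidden[:1], **kw)
        report = compare_classifiers(
            fm,
            classifiers,
            protocol=cfg.protocol,
            seed=_stage_seed(cfg.seed, "split"),
            k=cfg.k,
            groups=groups if cfg.split_by_subject else None,
        )
        efio.write_report(report.to_dict(), out / "report.json")
        report.table.to_csv(out / "report.tsv", sep="\t", index=False)
        for name, clf in classifiers.items():
            if getattr(clf, "model", None) is not None:
                efio.save_model(clf.model, out / f"model_{name.replace('-', '_')}.json")
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc
    return out
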