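"""End-to-end orchestration: simulate/load -> normalize -> Fisher -> select -> evaluate.

A :class:`PipelineConfig` is a single JSON-serializable document; unknown
keys are rejected so typos fail loudly, and every random behaviour traces
to the one run seed.  :func:`run_pipeline` writes all stage artifacts plus
a provenance record into the output directory and is reproducible: the
same config yields byte-identical numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field, fields
from datetime import datetime, timezone
from pathlib import Path

import numpy as np

from . import __version__
from . import fisher as fisher_mod
from . import preprocess, selector
from .data import MultiModalDataset, read_dataset, write_dataset
from .errors import ConfigurationError
from .evaluate import EvalConfig, cross_validate
from .selector import SelectorConfig
from .simulate import CohortSpec, generate_cohort

log = logging.getLogger("mmtfs")


def _from_dict(cls, obj: dict, context: str):
    known = {f.name for f in fields(cls)}
    unknown = set(obj) - known
    if unknown:
        raise ConfigurationError(f"unknown {context} config keys: {sorted(unknown)}")
    return cls(**obj)


@dataclass
class PipelineConfig:
    """Nested configuration of every stage plus the run seed."""

    seed: int = 0
    input_prefix: str | None = None            # load instead of simulate
    cohort: CohortSpec = field(default_factory=CohortSpec)
    normalization: dict = field(
        default_factory=lambda: {"imaging": "minmax", "snp": "zscore", "epsilon": preprocess.DEFAULT_EPS}
    )
    fisher: dict = field(
        default_factory=lambda: {"blocks": ["snp"], "top_m": None, "epsilon": preprocess.DEFAULT_EPS}
    )
    selector: SelectorConfig = field(default_factory=SelectorConfig)
    evaluation: dict = field(default_factory=lambda: {"n_folds": 5, "svm_C": 10.0})

    _NORM_KEYS = {"imaging", "snp", "epsilon"}
    _FISHER_KEYS = {"blocks", "top_m", "epsilon"}
    _EVAL_KEYS = {"n_folds", "svm_C"}

    def __post_init__(self) -> None:
        for name, allowed in (
            ("normalization", self._NORM_KEYS),
            ("fisher", self._FISHER_KEYS),
            ("evaluation", self._EVAL_KEYS),
        ):
            extra = set(getattr(self, name)) - allowed
            if extra:
                raise ConfigurationError(f"unknown {name} config keys: {sorted(extra)}")

    @classmethod
    def from_dict(cls, obj: dict) -> "PipelineConfig":
        obj = dict(obj)
        known = {f.name for f in fields(cls) if not f.name.startswith("_")}
        unknown = set(obj) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "cohort" in obj:
            obj["cohort"] = _from_dict(CohortSpec, obj["cohort"], "cohort")
        if "selector" in obj:
            obj["selector"] = _from_dict(SelectorConfig, obj["selector"], "selector")
        return cls(**obj)

    def to_dict(self) -> dict:
        out = asdict(self)
        return out

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def eval_config(self) -> EvalConfig:
        schemes = {k: v for k, v in self.normalization.items() if k != "epsilon"}
        return EvalConfig(
            schemes=schemes,
            norm_eps=self.normalization.get("epsilon", preprocess.DEFAULT_EPS),
            fisher_blocks=tuple(self.fisher.get("blocks", ["snp"])),
            top_m=self.fisher.get("top_m"),
            fisher_eps=self.fisher.get("epsilon", preprocess.DEFAULT_EPS),
            selector=self.selector,
            svm_C=self.evaluation.get("svm_C", 10.0),
        )


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not serializable: {type(obj)}")


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Execute every stage, writing artifacts and a provenance record.

    Artifacts: the cohort TSVs (when simulated) with ground truth, the
    whole-cohort normalization parameters and Fisher report (the CV
    refits both per fold), selection.json, cv_report.json (+ flat TSV)
    and provenance.json.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("[%(levelname)s %(name)s] %(message)s"))
    log.addHandler(handler)
    try:
        return _run_stages(config, out)
    finally:
        log.removeHandler(handler)


def _run_stages(config: PipelineConfig, out: Path) -> Path:
    stage = "simulate"
    try:
        if config.input_prefix:
            stage = "load"
            ds = read_dataset(config.input_prefix)
            log.info("load: read %d samples x %d features", ds.N, ds.d)
        else:
            spec = CohortSpec(**{**asdict(config.cohort), "seed": config.seed})
            ds, truth = generate_cohort(spec)
            write_dataset(ds, out / "cohort")
            truth.to_json(out / "cohort_truth.json")
            log.info("simulate: %d samples, blocks %s", ds.N, ds.block_names)

        eval_cfg = config.eval_config()

        stage = "normalize"
        ds_norm, norm_params = preprocess.normalize_dataset(
            ds, eval_cfg.schemes, eval_cfg.norm_eps
        )
        (out / "normalization_params.json").write_text(json.dumps(
            {
                name: {"scheme": p.scheme, "eps": p.eps,
                       "stat_a": p.stat_a, "stat_b": p.stat_b}
                for name, p in norm_params.items()
            },
            default=_json_default, indent=1,
        ))

        stage = "fisher"
        widths = {n: stop - start for n, (start, stop) in ds.modality_blocks}
        top_m = eval_cfg.top_m or widths.get("imaging", min(widths.values()))
        keep: list[int] = []
        fisher_records = {}
        for name, (start, stop) in ds.modality_blocks:
            if name in eval_cfg.fisher_blocks:
                rep = fisher_mod.fisher_scores(ds_norm.block(name), ds_norm.y, eval_cfg.fisher_eps)
                retained, _ = fisher_mod.select_top_m(rep, min(top_m, stop - start))
                fisher_records[name] = rep.to_records(ds.block_feature_names(name))
                keep.extend((retained + start).tolist())
            else:
                keep.extend(range(start, stop))
        (out / "fisher_report.json").write_text(
            json.dumps(fisher_records, default=_json_default, indent=1)
        )
        ds_red = ds_norm.subset_features(sorted(keep))
        log.info("fisher: reduced to %d features (top_m=%d)", ds_red.d, top_m)

        stage = "select"
        Y = selector.one_hot(ds_red.y, ds_red.class_order)
        weights, trace, converged = selector.fit(
            ds_red.X.T, Y, ds_red.modality_blocks, config.selector
        )
        sel, _ = selector.select_and_weight(
            weights, ds_red.X, config.selector.k_per_modality, config.selector.weight_norm
        )
        (out / "selection.json").write_text(json.dumps(
            {
                "converged": converged,
                "objective_trace": trace,
                "modalities": {
                    name: {
                        "selected_features": [ds_red.feature_names[i] for i in sel.selected[name]],
                        "raw_importance": sel.importance[sel.selected[name]],
                        "normalized_weights": sel.normalized_weights[name],
                    }
                    for name in ds_red.block_names
                },
            },
            default=_json_default, indent=1,
        ))
        log.info("select: converged=%s after %d iterations", converged, len(trace) - 1)

        stage = "evaluate"
        report = cross_validate(
            ds, eval_cfg, n_folds=config.evaluation.get("n_folds", 5), seed=config.seed
        )
        (out / "cv_report.json").write_text(
            json.dumps(report.to_dict(), default=_json_default, indent=1)
        )
        with (out / "cv_report.tsv").open("w") as fh:
            fh.write("fold\tmetric\tvalue\n")
            for i, f in enumerate(report.folds):
                for metric in ("accuracy", "sensitivity", "specificity"):
                    fh.write(f"{i}\t{metric}\t{getattr(f, metric)}\n")
            for metric in ("accuracy", "sensitivity", "specificity"):
                fh.write(f"mean\t{metric}\t{getattr(report, 'mean_' + metric)}\n")
        log.info("evaluate: mean accuracy %.1f%%", report.mean_accuracy)

        stage = "provenance"
        cfg_json = json.dumps(config.to_dict(), sort_keys=True)
        (out / "provenance.json").write_text(json.dumps(
            {
                "config": config.to_dict(),
                "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
                "seed": config.seed,
                "package_version": __version__,
                "numpy_version": np.__version__,
                "timestamp_utc": datetime.now(timezone.utc).isoformat(),
            },
            indent=1,
        ))
    except Exception as exc:
        raise ConfigurationError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return out
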