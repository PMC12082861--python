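"""End-to-end workflow: simulate/load -> select -> reduce -> augment ->
train -> evaluate, with a single master seed fanned out deterministically
per stage and a manifest hashing every artifact."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import augmentation as aug
from . import cohort as coh
from . import ensemble as ens
from . import evaluation as ev
from . import reduction as red
from . import selection as sel

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything a full run needs; loadable from YAML (see
    ``config_schema()`` for field documentation)."""

    # input: either a synthetic cohort spec or pre-existing CSVs
    cohort_dir: str | None = None        # directory with <block>.csv + labels.csv + truth.json
    n_samples: int = 144
    label_missing_count: int = 0
    continuous_effect: float = 1.0
    discrete_effect: float = 1.5
    # selection
    alpha: float = 0.05
    integration_rule: str = "all"
    discrete_method: str = "auto"
    correction: str | None = None
    # reduction
    L_per_block: int = 2
    pca_scale: bool = False
    # augmentation
    size_alpha: float = 0.05
    size_beta: float = 0.2
    size_agg: str = "max"
    smote_m: int = 1
    smote_k: int = 5
    force_augmentation: bool = False
    # ensemble / evaluation
    T: int = 10
    stacking_mode: str = "out_of_fold"
    K: int = 5
    augmentation_policy: str = "train_folds_only"
    # bookkeeping
    seed: int = 0
    out_dir: str = "run"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_SCHEMA = {
    "cohort_dir": (str, type(None)),
    "n_samples": (int,),
    "label_missing_count": (int,),
    "continuous_effect": (int, float),
    "discrete_effect": (int, float),
    "alpha": (int, float),
    "integration_rule": (str,),
    "discrete_method": (str,),
    "correction": (str, type(None)),
    "L_per_block": (int,),
    "pca_scale": (bool,),
    "size_alpha": (int, float),
    "size_beta": (int, float),
    "size_agg": (str,),
    "smote_m": (int,),
    "smote_k": (int,),
    "force_augmentation": (bool,),
    "T": (int,),
    "stacking_mode": (str,),
    "K": (int,),
    "augmentation_policy": (str,),
    "seed": (int,),
    "out_dir": (str,),
}


def config_schema() -> dict:
    """Field -> accepted YAML types, for ``--validate``."""
    return {k: [t.__name__ for t in v] for k, v in _SCHEMA.items()}


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> PipelineConfig:
    unknown = set(raw) - set(_SCHEMA)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key, value in raw.items():
        if not isinstance(value, _SCHEMA[key]):
            raise ValueError(
                f"config key {key!r}: expected {_SCHEMA[key]}, got {type(value)}"
            )
    cfg = PipelineConfig(**raw)
    validate_config(cfg)
    return cfg


def validate_config(cfg: PipelineConfig) -> None:
    if not 0 < cfg.alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if cfg.integration_rule not in sel.INTEGRATION_RULES:
        raise ValueError(f"integration_rule must be one of {sel.INTEGRATION_RULES}")
    if cfg.augmentation_policy not in ev.AUGMENTATION_POLICIES:
        raise ValueError(
            f"augmentation_policy must be one of {ev.AUGMENTATION_POLICIES}"
        )
    if cfg.stacking_mode not in ("in_sample", "out_of_fold"):
        raise ValueError("stacking_mode must be 'in_sample' or 'out_of_fold'")
    if cfg.K < 2:
        raise ValueError("K must be >= 2")
    if cfg.smote_m > cfg.smote_k:
        raise ValueError("smote_m must not exceed smote_k")
    if cfg.cohort_dir is not None and not Path(cfg.cohort_dir).exists():
        raise ValueError(f"cohort_dir {cfg.cohort_dir!r} does not exist")


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed: low 31 bits of sha256(master:stage)."""
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------


def stage_simulate(cfg: PipelineConfig, out: Path) -> coh.MultiOmicsCohort:
    if cfg.cohort_dir is not None:
        cohort = coh.MultiOmicsCohort.from_dir(cfg.cohort_dir)
    else:
        config = coh.default_config(
            seed=stage_seed(cfg.seed, "simulate"),
            n_samples=cfg.n_samples,
            label_missing_count=cfg.label_missing_count,
            continuous_effect=cfg.continuous_effect,
            discrete_effect=cfg.discrete_effect,
        )
        cohort = coh.generate_cohort(config)
    cohort = coh.filter_labelled(cohort)
    cohort.to_dir(out / "cohort")
    return cohort


def stage_select(cfg: PipelineConfig, cohort, out: Path) -> sel.SelectionReport:
    report = sel.select_features(
        cohort,
        alpha=cfg.alpha,
        rule=cfg.integration_rule,
        discrete_method=cfg.discrete_method,
        correction=cfg.correction,
    )
    report.to_csv(out / "selection_report.csv")
    return report


def stage_reduce(cfg: PipelineConfig, cohort, report, out: Path) -> red.ReducedDataset:
    design = red.assemble_design(
        cohort, report, L_per_block=cfg.L_per_block, scale=cfg.pca_scale
    )
    design.to_csv(out / "design.csv")
    for name, pca in design.transforms.items():
        pca.to_json(out / f"pca_{name}.json")
    return design


def stage_augment(cfg: PipelineConfig, cohort, report, design, out: Path):
    """Sample-size-driven augmentation of the full design.

    Returns (AugmentationResult | None, report dict).  Augmentation is
    skipped when the labelled cohort already meets the most demanding
    per-block requirement (unless forced).
    """
    block_sizes = aug.estimate_block_sizes(
        cohort, report, alpha=cfg.size_alpha, beta=cfg.size_beta, agg=cfg.size_agg
    )
    requirement = max(block_sizes.values()) if block_sizes else 0.0
    n_available = cohort.n_samples
    info = {
        "per_block_requirement": block_sizes,
        "overall_requirement": requirement,
        "n_available": n_available,
        "alpha": cfg.size_alpha,
        "beta": cfg.size_beta,
        "aggregation": cfg.size_agg,
        "seed": stage_seed(cfg.seed, "augment"),
    }
    if n_available >= requirement and not cfg.force_augmentation:
        info["skipped"] = f"skipped: n ({n_available}) >= requirement ({requirement})"
        result = None
    else:
        result = aug.smote(
            design.X,
            design.y,
            m=cfg.smote_m,
            k=cfg.smote_k,
            seed=stage_seed(cfg.seed, "augment"),
            discrete_cols=design.passthrough_columns,
        )
        info.update(
            {
                "m": cfg.smote_m,
                "k": cfg.smote_k,
                "n_augmented": int(len(result.y)),
                "meets_requirement": bool(len(result.y) >= requirement),
                "f1_before": result.f1_before,
                "f1_after": result.f1_after,
            }
        )
        result.to_frame().to_csv(out / "augmented.csv", index=False)
    with open(out / "augmentation_report.json", "w") as fh:
        json.dump(info, fh, indent=2, sort_keys=True)
    return result, info


def stage_train(cfg: PipelineConfig, design, augmented, out: Path) -> ens.EnsembleModel:
    if augmented is not None:
        X = augmented.X.to_numpy(dtype=float)
        y = np.asarray(augmented.y, dtype=int)
    else:
        X = design.X.to_numpy(dtype=float)
        y = np.asarray(design.y, dtype=int)
    model = ens.fit_ensemble(
        X,
        y,
        T=cfg.T,
        stacking_mode=cfg.stacking_mode,
        seed=stage_seed(cfg.seed, "train"),
        feature_names=list(design.X.columns),
    )
    ens.save_model(model, out / "model")
    return model


def stage_evaluate(cfg: PipelineConfig, design, out: Path) -> ev.EvalReport:
    report = ev.kfold_evaluate(
        design,
        K=cfg.K,
        seed=stage_seed(cfg.seed, "evaluate"),
        augmentation_policy=cfg.augmentation_policy,
        models=ev.default_model_factories(T=cfg.T, stacking_mode=cfg.stacking_mode),
        smote_m=cfg.smote_m,
        smote_k=cfg.smote_k,
    )
    report.to_json(out / "eval_report.json")
    report.metrics_csv(out / "metrics.csv")
    report.roc_csvs(out)
    return report


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path | None = None) -> Path:
    """Execute every stage in order and write ``manifest.json``.

    Re-running with an identical config reproduces byte-identical
    artifacts (no timestamps are recorded).
    """
    validate_config(cfg)
    out = Path(out_dir if out_dir is not None else cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: dict[str, str] = {}

    def _run(name, fn, *args):
        try:
            result = fn(cfg, *args)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        stages[name] = "ok"
        return result

    cohort = _run("simulate", stage_simulate, out)
    report = _run("select", stage_select, cohort, out)
    design = _run("reduce", stage_reduce, cohort, report, out)
    augmented, aug_info = _run("augment", stage_augment, cohort, report, design, out)
    if "skipped" in aug_info:
        stages["augment"] = aug_info["skipped"]
    _run("train", stage_train, design, augmented, out)
    _run("evaluate", stage_evaluate, design, out)

    files = {
        str(p.relative_to(out)): _sha256(p)
        for p in sorted(out.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = {"config": cfg.to_dict(), "stages": stages, "files": files}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
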